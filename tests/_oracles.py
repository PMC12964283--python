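"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np

import allomed as am


def brute_force_entropy_weights(z: np.ndarray) -> np.ndarray:
    """Literal transcription of the entropy-method formulas, element by element."""
    n, m = z.shape
    e = np.empty(m)
    for j in range(m):
        colsum = sum(z[i, j] for i in range(n))
        s = 0.0
        for i in range(n):
            p = z[i, j] / colsum
            if p > 0:
                s += p * np.log(p)
        e[j] = -s / np.log(n)
    d = 1.0 - e
    return d / d.sum()


def brute_force_sse(values, k):
    """Minimal within-class SSE over every contiguous partition into k classes."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def sse(seg):
        return float(((seg - seg.mean()) ** 2).sum())

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(sse(x[a:b]) for a, b in zip(bounds, bounds[1:]))
        best = min(best, total)
    return best


def partition_sse(values, breaks: am.JenksBreaks) -> float:
    x = np.asarray(values, dtype=float)
    cls = am.assign_classes(x, breaks)
    return float(sum(((x[cls == c] - x[cls == c].mean()) ** 2).sum()
                     for c in np.unique(cls)))
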