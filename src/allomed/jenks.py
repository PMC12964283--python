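"""Fisher-Jenks natural-breaks classification.

Exact 1-D optimal classification: split sorted values into k contiguous
classes minimizing the total within-class sum of squared deviations, by
dynamic programming over class boundaries (O(k n^2) with prefix sums).
Used only for binning map-ready exports, never inside the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["JenksBreaks", "jenks_breaks", "assign_classes"]


@dataclass(frozen=True)
class JenksBreaks:
    """k+1 ordered break values; first/last are the data min/max.

    Value v belongs to class m (1-based) when ``breaks[m-1] < v <=
    breaks[m]``, except class 1 which also includes the minimum.
    """

    breaks: tuple[float, ...]
    k: int
    gvf: float  # goodness of variance fit, 1 - SSE_within / SSE_total


def _sse_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums for O(1) within-class SSE of x[i..j] (inclusive)."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return s1, s2


def _sse(s1: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    n = j - i + 1
    total = s1[j + 1] - s1[i]
    return (s2[j + 1] - s2[i]) - total * total / n


def jenks_breaks(values, k: int) -> JenksBreaks:
    """Optimal k-class natural breaks of a numeric list.

    Requires at least k distinct values; raises otherwise.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    if x.size == 0:
        raise ValidationError("cannot classify an empty list")
    if not np.all(np.isfinite(x)):
        raise ValidationError("values must be finite")
    n_distinct = len(np.unique(x))
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n_distinct:
        raise ValidationError(f"k={k} exceeds the {n_distinct} distinct value(s)")

    n = len(x)
    s1, s2 = _sse_matrix(x)

    # cost[c][j]: minimal SSE of splitting x[0..j] into c+1 classes.
    cost = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)  # start index of the last class
    for j in range(n):
        cost[0, j] = _sse(s1, s2, 0, j)
    for c in range(1, k):
        for j in range(c, n):
            best, arg = np.inf, c
            for i in range(c, j + 1):
                val = cost[c - 1, i - 1] + _sse(s1, s2, i, j)
                if val < best:
                    best, arg = val, i
            cost[c, j] = best
            split[c, j] = arg

    # Backtrack class boundaries (upper value of each class).
    breaks = [float(x[-1])]
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = split[c, j]
        breaks.append(float(x[i - 1]))
        j = i - 1
    breaks.append(float(x[0]))
    breaks.reverse()

    sse_within = float(cost[k - 1, n - 1])
    sse_total = _sse(s1, s2, 0, n - 1)
    gvf = 1.0 if sse_total == 0 else 1.0 - sse_within / sse_total
    return JenksBreaks(tuple(breaks), k, gvf)


def assign_classes(values, breaks: JenksBreaks) -> np.ndarray:
    """1-based class index for each value under the given breaks."""
    x = np.asarray(list(values), dtype=float)
    edges = np.asarray(breaks.breaks[1:-1])
    return (np.searchsorted(edges, x, side="left") + 1).astype(int)
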