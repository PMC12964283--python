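"""Entropy-weighted composite supply index.

The three raw M&H indicators (institutions, beds, doctors) are combined
into one supply level per city-year in three steps:

1. **Range normalization** over the pooled city x year panel:
   ``Z = (x - min) / (max - min)``, optionally followed by a small positive
   shift ``Z' = (Z + eps) / (1 + eps)`` so the composite stays strictly
   positive (it is later fed to a logarithm).
2. **Entropy weighting**: with ``p_ij = Z_ij / sum_i Z_ij`` and information
   entropy ``e_j = -(1/ln n) * sum_i p_ij ln p_ij`` (``0 ln 0 := 0``), the
   weight of indicator j is ``w_j = (1 - e_j) / sum_k (1 - e_k)`` — more
   dispersed indicators carry more information and weigh more. The reference
   study reports weights 0.2774 / 0.3581 / 0.3645 for institutions / beds /
   doctors on its yearbook panel.
3. **Weighted summation**: ``M_i = sum_j Z_ij * w_j``.

Normalization and entropy are pooled across all years by default (a single
weight triple for the whole study window); per-year weighting is available
via :func:`composite_pipeline`'s ``per_year`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .panel import INDICATOR_COLUMNS, PanelDataset

__all__ = [
    "NormalizedMatrix",
    "WeightVector",
    "CompositeSeries",
    "range_normalize",
    "entropy_weights",
    "composite_index",
    "composite_pipeline",
    "total_supply_series",
]

DEFAULT_EPSILON = 1e-4


@dataclass(frozen=True)
class NormalizedMatrix:
    """Range-normalized indicator matrix with its (city_id, year) keys."""

    values: pd.DataFrame = field(repr=False)  # columns = indicators
    keys: pd.DataFrame = field(repr=False)    # columns = city_id, year
    epsilon: float = 0.0


@dataclass(frozen=True)
class WeightVector:
    """Entropy-derived indicator weights (sum to 1)."""

    weights: pd.Series = field(repr=False)

    def __post_init__(self):
        w = self.weights.to_numpy(dtype=float)
        if abs(w.sum() - 1.0) > 1e-12 or (w < 0).any() or (w > 1).any():
            raise ValidationError("weights must lie in [0, 1] and sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {str(k): float(v) for k, v in self.weights.items()}


@dataclass(frozen=True)
class CompositeSeries:
    """Composite supply level per (city_id, year)."""

    frame: pd.DataFrame = field(repr=False)  # columns: city_id, year, m_index
    meta: dict = field(default_factory=dict)


def range_normalize(
    panel: PanelDataset,
    epsilon: float = DEFAULT_EPSILON,
    columns: tuple[str, ...] = INDICATOR_COLUMNS,
) -> NormalizedMatrix:
    """Min-max normalize indicator columns over the pooled panel.

    A constant column has no range and is rejected by name. ``epsilon > 0``
    applies the shift-rescale ``(Z + eps) / (1 + eps)`` mapping [0, 1] into
    (0, 1]; ``epsilon = 0`` disables it.
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    frame = panel.frame
    out = {}
    for col in columns:
        x = frame[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi <= lo:
            raise ValidationError(f"indicator column {col!r} is constant; range normalization undefined")
        z = (x - lo) / (hi - lo)
        if epsilon > 0:
            z = (z + epsilon) / (1.0 + epsilon)
        out[col] = z
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=frame.index),
        keys=frame[["city_id", "year"]].copy(),
        epsilon=epsilon,
    )


def entropy_weights(z: NormalizedMatrix | pd.DataFrame) -> WeightVector:
    """Entropy-method weights from a non-negative normalized matrix."""
    values = z.values if isinstance(z, NormalizedMatrix) else z
    arr = values.to_numpy(dtype=float)
    n, _ = arr.shape
    if n < 2:
        raise ValidationError("entropy weighting needs at least 2 observations")
    if (arr < 0).any():
        raise ValidationError("normalized values must be non-negative")
    colsum = arr.sum(axis=0)
    if (colsum <= 0).any():
        bad = [values.columns[j] for j in np.where(colsum <= 0)[0]]
        raise ValidationError(f"column(s) with no positive entry: {bad}")

    p = arr / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)  # 0 ln 0 := 0
    e = -plogp.sum(axis=0) / np.log(n)
    d = 1.0 - e  # information utility
    if d.sum() <= 1e-15:
        raise ValidationError("all indicators perfectly uniform; entropy weights undefined")
    w = d / d.sum()
    return WeightVector(pd.Series(w, index=values.columns))


def composite_index(z: NormalizedMatrix, w: WeightVector) -> CompositeSeries:
    """Weighted summation ``M_i = sum_j Z_ij w_j`` per observation."""
    if list(z.values.columns) != list(w.weights.index):
        raise ValidationError(
            f"weight/indicator mismatch: {list(w.weights.index)} vs {list(z.values.columns)}"
        )
    m = z.values.to_numpy(dtype=float) @ w.weights.to_numpy(dtype=float)
    frame = z.keys.copy()
    frame["m_index"] = m
    return CompositeSeries(
        frame=frame.reset_index(drop=True),
        meta={"weights": w.as_dict(), "epsilon": z.epsilon, "scope": "pooled"},
    )


def composite_pipeline(
    panel: PanelDataset,
    epsilon: float = DEFAULT_EPSILON,
    per_year: bool = False,
) -> tuple[CompositeSeries, WeightVector]:
    """Normalize, weight and combine in one call.

    ``per_year=True`` repeats normalization and weighting within each year
    instead of pooling; the default pooled scope yields one weight triple
    for the whole window (the per-year weights are then averaged only for
    reporting, never used).
    """
    if not per_year:
        z = range_normalize(panel, epsilon=epsilon)
        w = entropy_weights(z)
        return composite_index(z, w), w

    pieces = []
    weight_rows = []
    for year in panel.years:
        sub = PanelDataset(panel.frame[panel.frame["year"] == year].reset_index(drop=True))
        z = range_normalize(sub, epsilon=epsilon)
        w = entropy_weights(z)
        pieces.append(composite_index(z, w).frame)
        weight_rows.append(w.weights)
    mean_w = pd.concat(weight_rows, axis=1).mean(axis=1)
    mean_w = mean_w / mean_w.sum()
    frame = pd.concat(pieces, ignore_index=True).sort_values(["city_id", "year"]).reset_index(drop=True)
    series = CompositeSeries(frame=frame, meta={"epsilon": epsilon, "scope": "per_year"})
    return series, WeightVector(mean_w)


def total_supply_series(panel: PanelDataset) -> CompositeSeries:
    """Raw resource total (institutions + beds + doctors) as the supply level.

    Unlike the range-normalized composite, the total is proportional to the
    generated power-law resource quantity, so log-log fits on it recover
    generator exponents exactly. Used for fixture-recovery checks and
    available as a pipeline option.
    """
    frame = panel.frame[["city_id", "year"]].copy()
    frame["m_index"] = panel.frame[list(INDICATOR_COLUMNS)].sum(axis=1)
    return CompositeSeries(frame=frame, meta={"scope": "raw_total"})
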