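"""Allometric scaling-exponent estimation.

The allometric growth model relates the M&H resource supply level M to the
permanent resident population P through a power law

    M = a * P**b,        ln M = ln a + b ln P,

and estimates the scale factor ``a`` and scaling exponent ``b`` by ordinary
least squares on natural logs. ``b = 1`` means proportional growth; ``b``
above (below) 1 means resources outpace (lag) population. ``b = 0.85`` is
the coordination benchmark used by the typology downstream.

Two estimation scopes are used, named after how the results sections of
urban-scaling studies use them (their verbal definitions sometimes read the
opposite way — see docs/methods.md):

* **vertical**: one cross-city regression per year — tracks the exponent of
  the whole city system through time;
* **horizontal**: one over-time regression per city within a period window
  — maps which cities' resources outpace their population.

The core objects follow the Model/Results convention:
``AllometricModel(population, supply).fit()`` returns an
:class:`AllometricResults` carrying the exponent, intercept, fit quality and
a ``summary()`` table. ``fit_allometry``, ``vertical_series`` and
``horizontal_fits`` are thin functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .entropy import CompositeSeries
from .exceptions import ValidationError
from .panel import PanelDataset

__all__ = [
    "AllometricModel",
    "AllometricResults",
    "FitScope",
    "StagePartition",
    "fit_allometry",
    "vertical_series",
    "horizontal_fits",
    "stage_partition",
    "STAGE_PRP_EXPANSION",
    "STAGE_BASIC_COORDINATION",
    "STAGE_MH_EXPANSION",
]

logger = logging.getLogger(__name__)

STAGE_PRP_EXPANSION = "PRP expansion"
STAGE_BASIC_COORDINATION = "basic coordination"
STAGE_MH_EXPANSION = "M&H expansion"

#: Stage thresholds on the exponent: below 0.85 population outruns supply,
#: 0.85-1 the two are basically coordinated, at or above 1 supply outruns.
_COORDINATION_THRESHOLD = 0.85
_PROPORTIONAL_THRESHOLD = 1.0


@dataclass(frozen=True)
class FitScope:
    """What a fit covers: one year across cities, or one city across years."""

    mode: str  # "vertical" | "horizontal"
    year: int | None = None
    city_id: str | None = None
    period: tuple[int, int] | None = None

    def describe(self) -> str:
        if self.mode == "vertical":
            return f"vertical, year {self.year}"
        lo, hi = self.period if self.period else ("?", "?")
        return f"horizontal, city {self.city_id}, {lo}-{hi}"


class AllometricModel:
    """Log-log OLS model of supply level on population.

    Parameters
    ----------
    population, supply : array-like
        Strictly positive, same length (>= 3). Offending records are named
        in the error if not.
    scope : FitScope, optional
        Bookkeeping tag describing what the fit covers.
    """

    def __init__(self, population, supply, scope: FitScope | None = None):
        p = np.asarray(population, dtype=float)
        m = np.asarray(supply, dtype=float)
        if p.shape != m.shape or p.ndim != 1:
            raise ValidationError("population and supply must be 1-D arrays of equal length")
        if len(p) < 3:
            raise ValidationError(f"need >= 3 observations, got {len(p)}")
        bad_p = np.where(p <= 0)[0]
        if len(bad_p):
            raise ValidationError(f"non-positive population at positions {bad_p.tolist()[:10]}")
        bad_m = np.where(m <= 0)[0]
        if len(bad_m):
            raise ValidationError(f"non-positive supply level at positions {bad_m.tolist()[:10]}")
        self.ln_p = np.log(p)
        self.ln_m = np.log(m)
        if np.ptp(self.ln_p) <= 1e-300 or np.var(self.ln_p) == 0.0:
            raise ValidationError("population values all equal; scaling exponent unidentified")
        self.scope = scope or FitScope(mode="vertical")

    def fit(self) -> "AllometricResults":
        res = sm.OLS(self.ln_m, sm.add_constant(self.ln_p)).fit()
        ln_a, b = float(res.params[0]), float(res.params[1])
        r2 = float(res.rsquared)
        # Collinear fits can give 1 + eps; a constant response gives 0/0.
        r2 = 0.0 if not np.isfinite(r2) else min(max(r2, 0.0), 1.0)
        return AllometricResults(
            exponent=b, ln_intercept=ln_a, r_squared=r2,
            n_obs=len(self.ln_p), scope=self.scope, model=self,
        )


@dataclass(frozen=True)
class AllometricResults:
    """Fitted allometric scaling relationship.

    Attributes
    ----------
    exponent : float
        The allometric growth coefficient b (slope of ln M on ln P).
    ln_intercept : float
        ln a, the log scale factor.
    r_squared : float
        Coefficient of determination of the log-log regression.
    """

    exponent: float
    ln_intercept: float
    r_squared: float
    n_obs: int
    scope: FitScope
    model: AllometricModel = field(repr=False, compare=False)

    @property
    def intercept(self) -> float:
        """Scale factor a on the raw scale."""
        return float(np.exp(self.ln_intercept))

    def predict(self, population) -> np.ndarray:
        """Fitted supply level a * P**b."""
        p = np.asarray(population, dtype=float)
        return np.exp(self.ln_intercept + self.exponent * np.log(p))

    def plot(self, ax=None):
        """Log-log scatter with the fitted scaling line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.ln_p, self.model.ln_m, s=18, alpha=0.7)
        xs = np.linspace(self.model.ln_p.min(), self.model.ln_p.max(), 50)
        ax.plot(xs, self.ln_intercept + self.exponent * xs, color="C3",
                label=f"b = {self.exponent:.3f}, R² = {self.r_squared:.3f}")
        ax.set_xlabel("ln population")
        ax.set_ylabel("ln supply level")
        ax.set_title(self.scope.describe())
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Allometric scaling fit (OLS on natural logs)",
            f"  scope      : {self.scope.describe()}",
            f"  exponent b : {self.exponent:.4f}",
            f"  ln a       : {self.ln_intercept:.4f}",
            f"  R-squared  : {self.r_squared:.4f}",
            f"  n obs      : {self.n_obs}",
        ]
        return "\n".join(lines)


def fit_allometry(pairs: Iterable[tuple[float, float]] | None = None,
                  population=None, supply=None,
                  scope: FitScope | None = None) -> AllometricResults:
    """OLS scaling fit from (P, M) pairs or separate arrays."""
    if pairs is not None:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError("pairs must be (P, M) tuples")
        population, supply = arr[:, 0], arr[:, 1]
    return AllometricModel(population, supply, scope=scope).fit()


def _joined(panel: PanelDataset, composite: CompositeSeries) -> pd.DataFrame:
    merged = panel.frame[["city_id", "year", "prp"]].merge(
        composite.frame, on=["city_id", "year"], how="inner"
    )
    if merged.empty:
        raise ValidationError("panel and composite series share no (city_id, year) keys")
    return merged


def vertical_series(panel: PanelDataset, composite: CompositeSeries) -> list[AllometricResults]:
    """One cross-city fit per year, ordered by year.

    Years with fewer than 3 usable cities are excluded with a logged
    warning rather than an error.
    """
    merged = _joined(panel, composite)
    out: list[AllometricResults] = []
    for year, grp in merged.groupby("year", sort=True):
        usable = grp[(grp["prp"] > 0) & (grp["m_index"] > 0)]
        if len(usable) < 3:
            logger.warning("year %s skipped: only %d usable cities", year, len(usable))
            continue
        model = AllometricModel(
            usable["prp"], usable["m_index"], scope=FitScope(mode="vertical", year=int(year))
        )
        out.append(model.fit())
    return out


def horizontal_fits(
    panel: PanelDataset,
    composite: CompositeSeries,
    period: tuple[int, int],
) -> tuple[dict[str, AllometricResults], list[dict]]:
    """One per-city over-time fit within an inclusive year window.

    Returns ``(fits, exclusions)``; a city failing the preconditions
    (fewer than 3 usable years, constant population, non-positive values)
    lands in the exclusion list with a reason, never silently dropped.
    """
    lo, hi = period
    if hi < lo:
        raise ValidationError(f"empty period window {period}")
    merged = _joined(panel, composite)
    merged = merged[(merged["year"] >= lo) & (merged["year"] <= hi)]
    fits: dict[str, AllometricResults] = {}
    exclusions: list[dict] = []
    for city, grp in merged.groupby("city_id", sort=True):
        usable = grp[(grp["prp"] > 0) & (grp["m_index"] > 0)]
        if len(usable) < 3:
            exclusions.append({"city_id": city, "reason": f"only {len(usable)} usable years in window"})
            continue
        try:
            model = AllometricModel(
                usable["prp"], usable["m_index"],
                scope=FitScope(mode="horizontal", city_id=str(city), period=(lo, hi)),
            )
        except ValidationError as exc:
            exclusions.append({"city_id": city, "reason": str(exc)})
            continue
        fits[str(city)] = model.fit()
    return fits, exclusions


@dataclass(frozen=True)
class StagePartition:
    """Contiguous year ranges labelled by coordination stage."""

    ranges: tuple[tuple[int, int, str], ...]  # (start, end, label)

    def as_records(self) -> list[dict]:
        return [{"start": s, "end": e, "stage": lbl} for s, e, lbl in self.ranges]


def _stage_label(b: float) -> str:
    if b < _COORDINATION_THRESHOLD:
        return STAGE_PRP_EXPANSION
    if b < _PROPORTIONAL_THRESHOLD:
        return STAGE_BASIC_COORDINATION
    return STAGE_MH_EXPANSION


def stage_partition(series: Sequence[AllometricResults]) -> StagePartition:
    """Label each year of a vertical series and merge consecutive equal labels.

    Years with b < 0.85 are "PRP expansion" (population outruns supply),
    0.85 <= b < 1 "basic coordination", b >= 1 "M&H expansion".
    """
    if not series:
        raise ValidationError("cannot partition an empty series")
    items = sorted(series, key=lambda r: r.scope.year if r.scope.year is not None else 0)
    ranges: list[tuple[int, int, str]] = []
    for res in items:
        year = res.scope.year
        if year is None:
            raise ValidationError("stage_partition needs vertical fits with a year scope")
        label = _stage_label(res.exponent)
        if ranges and ranges[-1][2] == label and ranges[-1][1] == year - 1:
            ranges[-1] = (ranges[-1][0], year, label)
        else:
            ranges.append((year, year, label))
    return StagePartition(tuple(ranges))
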