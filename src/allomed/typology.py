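"""Six-level allometric growth typology and change analysis.

Exponents are binned by half-open, lower-inclusive intervals around the
b = 0.85 coordination benchmark:

=========  ===============  =============================================
label      interval         reading
=========  ===============  =============================================
PAG3       3 <= b           strong expansion of M&H resources
PAG2       1 <= b < 3       weak expansion of M&H resources
PAG1       0.85 <= b < 1    essential alignment of resources with PRP
NAG1       0.5 <= b < 0.85  weak expansion of PRP
NAG2       0 <= b < 0.5     strong expansion of PRP
NAG3       b < 0            shrinkage of resources relative to PRP
=========  ===============  =============================================

Classes carry an ordinal rank (NAG3 = 0 ... PAG3 = 5) ordered by the
b-interval, matching the domain language of cities "upgrading" toward
positive allometry; whether the top class is desirable is a policy
question the code does not encode. Between-period comparisons yield one of
five change kinds: upgraded / downgraded across levels, improved / declined
within a level (by the sign of the exponent change), or stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .allometry import AllometricResults
from .exceptions import ValidationError

__all__ = [
    "AllometryClass",
    "ChangeRecord",
    "CLASSES",
    "classify_exponent",
    "change_type",
    "summarize_counts",
    "classification_table",
]

_CHANGE_TOL = 1e-9


@dataclass(frozen=True)
class AllometryClass:
    label: str
    rank: int
    lower: float  # inclusive
    upper: float  # exclusive
    description: str

    def contains(self, b: float) -> bool:
        return self.lower <= b < self.upper

    @property
    def positive(self) -> bool:
        return self.label.startswith("PAG")


#: Ordered low to high; intervals partition the real line.
CLASSES: tuple[AllometryClass, ...] = (
    AllometryClass("NAG3", 0, -math.inf, 0.0, "shrinkage of M&H resources relative to PRP"),
    AllometryClass("NAG2", 1, 0.0, 0.5, "strong expansion of PRP"),
    AllometryClass("NAG1", 2, 0.5, 0.85, "weak expansion of PRP"),
    AllometryClass("PAG1", 3, 0.85, 1.0, "essential alignment of M&H resources with PRP"),
    AllometryClass("PAG2", 4, 1.0, 3.0, "weak expansion of M&H resources"),
    AllometryClass("PAG3", 5, 3.0, math.inf, "strong expansion of M&H resources"),
)

_BY_LABEL = {c.label: c for c in CLASSES}


def classify_exponent(b: float) -> AllometryClass:
    """Map a finite exponent to its unique class (lower bounds inclusive)."""
    if not math.isfinite(b):
        raise ValidationError(f"exponent must be finite, got {b!r}")
    for cls in CLASSES:
        if cls.contains(b):
            return cls
    raise AssertionError("intervals partition the line")  # pragma: no cover


@dataclass(frozen=True)
class ChangeRecord:
    """Between-period transition of one city's allometric class."""

    city_id: str
    class_p1: AllometryClass
    class_p2: AllometryClass
    delta_b: float
    change_kind: str  # upgraded | improved-within-level | stable | declined-within-level | downgraded


def change_type(fit1: AllometricResults, fit2: AllometricResults) -> ChangeRecord:
    """Classify the change from period-1 to period-2 fit for one city.

    Rank movement dominates; within a level the sign of the exponent change
    decides (|delta| <= 1e-9 counts as stable).
    """
    c1, c2 = fit1.scope.city_id, fit2.scope.city_id
    if c1 != c2:
        raise ValidationError(f"fits are for different cities: {c1!r} vs {c2!r}")
    k1 = classify_exponent(fit1.exponent)
    k2 = classify_exponent(fit2.exponent)
    delta = fit2.exponent - fit1.exponent
    if k2.rank > k1.rank:
        kind = "upgraded"
    elif k2.rank < k1.rank:
        kind = "downgraded"
    elif delta > _CHANGE_TOL:
        kind = "improved-within-level"
    elif delta < -_CHANGE_TOL:
        kind = "declined-within-level"
    else:
        kind = "stable"
    return ChangeRecord(str(c1), k1, k2, delta, kind)


def _share(count: int, total: int) -> float:
    """Percentage share rounded half-up to 2 decimals (24/41 -> 58.54)."""
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_counts(fits: Mapping[str, AllometricResults]) -> dict:
    """Per-class counts and percentage shares, plus positive/negative totals."""
    if not fits:
        raise ValidationError("no fits to summarize")
    total = len(fits)
    counts = {c.label: 0 for c in CLASSES}
    for res in fits.values():
        counts[classify_exponent(res.exponent).label] += 1
    positive = sum(counts[c.label] for c in CLASSES if c.positive)
    negative = total - positive
    return {
        "total": total,
        "counts": counts,
        "shares": {label: _share(n, total) for label, n in counts.items()},
        "positive": positive,
        "negative": negative,
        "positive_share": _share(positive, total),
        "negative_share": _share(negative, total),
    }


def classification_table(fits: Mapping[str, AllometricResults]) -> pd.DataFrame:
    """Long-format classification table (city, period, b, label, rank)."""
    rows = []
    for city, res in sorted(fits.items()):
        cls = classify_exponent(res.exponent)
        period = res.scope.period
        rows.append({
            "city_id": city,
            "period": f"{period[0]}-{period[1]}" if period else "",
            "exponent_b": res.exponent,
            "label": cls.label,
            "rank": cls.rank,
        })
    return pd.DataFrame(rows)


def class_by_label(label: str) -> AllometryClass:
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise ValidationError(f"unknown class label {label!r}") from None
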