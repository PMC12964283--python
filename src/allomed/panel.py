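"""City-year panel container.

A :class:`PanelDataset` holds long-format records of the permanent resident
population (PRP) and the three raw medical & healthcare (M&H) supply
indicators — institutions, hospital beds and doctors — for a set of cities
over a range of years, plus any number of optional driver columns (raw
components of the ten driver ratios, or the ratios themselves).

The container is a thin validated wrapper over a :class:`pandas.DataFrame`;
all analysis modules accept and return plain DataFrames where possible and
use this class only at the trust boundary (file input, generator output).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError

#: Columns every panel must carry.
REQUIRED_COLUMNS = ("city_id", "year", "prp", "institutions", "beds", "doctors")

#: The three raw supply indicators combined into the composite index.
INDICATOR_COLUMNS = ("institutions", "beds", "doctors")


@dataclass(frozen=True)
class PanelDataset:
    """Validated long-format city-year panel.

    Parameters
    ----------
    frame : pandas.DataFrame
        Must contain :data:`REQUIRED_COLUMNS`; extra columns (drivers) are
        preserved untouched. Use :meth:`from_frame` / :meth:`read_csv` so the
        invariants below are enforced:

        * ``(city_id, year)`` pairs unique,
        * ``prp`` strictly positive,
        * indicator columns non-negative,
        * no missing values in required columns.
    """

    frame: pd.DataFrame = field(repr=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PanelDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"panel is missing required columns: {missing}")

        frame = frame.copy()
        frame["year"] = frame["year"].astype(int)
        for col in ("prp", *INDICATOR_COLUMNS):
            try:
                frame[col] = pd.to_numeric(frame[col])
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"non-numeric value in column {col!r}: {exc}") from exc

        na_rows = frame.index[frame[list(REQUIRED_COLUMNS)].isna().any(axis=1)]
        if len(na_rows):
            raise ValidationError(f"missing values in required columns at rows {list(na_rows[:10])}")

        dup = frame.duplicated(subset=["city_id", "year"], keep=False)
        if dup.any():
            offenders = frame.loc[dup, ["city_id", "year"]].head(10)
            raise ValidationError(
                "duplicate (city_id, year) keys at rows "
                f"{list(offenders.index)}: {offenders.to_dict('records')}"
            )

        bad_prp = frame.index[frame["prp"] <= 0]
        if len(bad_prp):
            raise ValidationError(f"non-positive PRP at rows {list(bad_prp[:10])}")

        for col in INDICATOR_COLUMNS:
            bad = frame.index[frame[col] < 0]
            if len(bad):
                raise ValidationError(f"negative {col} at rows {list(bad[:10])}")

        frame = frame.sort_values(["city_id", "year"], kind="mergesort").reset_index(drop=True)
        return cls(frame)

    @classmethod
    def read_csv(cls, path) -> "PanelDataset":
        """Read and validate a UTF-8 CSV panel (header row required)."""
        try:
            frame = pd.read_csv(path, encoding="utf-8")
        except (pd.errors.ParserError, UnicodeDecodeError, pd.errors.EmptyDataError) as exc:
            raise ValidationError(f"cannot parse panel CSV {path}: {exc}") from exc
        return cls.from_frame(frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, encoding="utf-8")

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.frame.to_csv(buf, index=False)
        return buf.getvalue()

    # -- conveniences -------------------------------------------------------

    @property
    def cities(self) -> list:
        return sorted(self.frame["city_id"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())

    @property
    def driver_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in REQUIRED_COLUMNS]

    def subset_years(self, start: int, end: int) -> "PanelDataset":
        """Rows with ``start <= year <= end`` (inclusive window)."""
        mask = (self.frame["year"] >= start) & (self.frame["year"] <= end)
        return PanelDataset(self.frame.loc[mask].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)
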