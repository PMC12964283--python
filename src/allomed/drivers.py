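"""Boosted-regression-tree decomposition of allometric-growth drivers.

The per-city scaling exponent (the response) is modelled as a nonlinear
function of ten socio-economic driver ratios with stagewise gradient
boosting: squared-error loss, depth-limited regression trees (interaction
depth = "tree complexity"), shrinkage (learning rate 0.01 by default) and
stochastic subsampling (bag fraction 0.75). The number of trees is chosen by
k-fold cross-validated error, gbm.step-style: each fold's validation error
is tracked over the whole staged sequence and the ensemble is cut at the
tree count minimizing mean CV error, then refit on all rows.

Outputs mirror the two standard BRT summaries:

* **relative influence** — per-feature percentages of the ensemble's split
  improvement, summing to 100 (the "contribution rate" of each driver);
* **marginal-effect profiles** — model predictions along one feature's
  observed range with every other feature pinned at its mean (a
  ceteris-paribus profile; averaged partial dependence is available as an
  alternative).

The gradient-boosting machinery is scikit-learn's
:class:`~sklearn.ensemble.GradientBoostingRegressor`; the CV tree selection,
influence tabulation and profiles are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .allometry import AllometricResults
from .exceptions import ValidationError
from .panel import PanelDataset

__all__ = [
    "RATIO_DEFINITIONS",
    "BRTConfig",
    "DriverModel",
    "DriverResults",
    "build_driver_table",
    "fit_brt",
    "relative_influence",
    "marginal_profile",
]

#: ratio name -> (influencing-factor name, numerator column, denominator
#: column, scale). Scale 100 turns a fraction into percent; per-capita GDP
#: (yuan/person) and population density (persons/km^2) stay on their
#: natural scales.
RATIO_DEFINITIONS: dict[str, tuple[str, str, str, float]] = {
    "per_capita_gdp": ("economic development level", "gdp", "prp", 1.0),
    "tertiary_share": ("industrial structure", "tertiary_value_added", "gdp", 100.0),
    "fiscal_ratio": ("fiscal self-sufficiency capacity", "fiscal_revenue", "fiscal_expenditure", 100.0),
    "medical_investment": ("medical investment", "gov_mh_expenditure", "fiscal_expenditure", 100.0),
    "urbanization_rate": ("urban development level", "urban_population", "prp", 100.0),
    "population_attraction": ("population attraction", "prp", "registered_population", 100.0),
    "population_density": ("population concentration", "prp", "admin_area_km2", 1.0),
    "income_ratio": ("urban-rural income gap", "urban_income", "rural_income", 100.0),
    "medical_consumption": ("medical consumption", "household_mh_expenditure", "living_expenses", 100.0),
    "aging_rate": ("aging", "pop_aged_65plus", "prp", 100.0),
}

FEATURE_NAMES = tuple(RATIO_DEFINITIONS)
RESPONSE_COLUMN = "exponent_b"


def build_driver_table(
    panel: PanelDataset,
    fits: Mapping[str, AllometricResults],
    period: tuple[int, int],
) -> pd.DataFrame:
    """Driver table: one row per city, ten ratio features + exponent response.

    Features are period means of the annual ratios. If the panel already
    carries a ratio column by name it is used directly; otherwise the ratio
    is computed from its raw components, and a missing component is reported
    by the influencing-factor name it breaks.
    """
    lo, hi = period
    frame = panel.frame
    window = frame[(frame["year"] >= lo) & (frame["year"] <= hi)].copy()
    if window.empty:
        raise ValidationError(f"no panel rows in period {period}")

    for name, (factor, num, den, scale) in RATIO_DEFINITIONS.items():
        if name in window.columns:
            continue
        for comp in (num, den):
            if comp not in window.columns:
                raise ValidationError(
                    f"cannot compute {factor!r} ({name}): panel lacks component column {comp!r}"
                )
        window[name] = scale * window[num] / window[den]

    means = window.groupby("city_id", sort=True)[list(FEATURE_NAMES)].mean()
    rows = []
    for city, res in sorted(fits.items()):
        if city not in means.index:
            raise ValidationError(f"fit provided for city {city!r} absent from panel window")
        row = {"city_id": city, **means.loc[city].to_dict(), RESPONSE_COLUMN: res.exponent}
        rows.append(row)
    if not rows:
        raise ValidationError("no cities shared between fits and panel")
    table = pd.DataFrame(rows)
    if table[list(FEATURE_NAMES)].isna().any().any():
        raise ValidationError("driver table contains missing feature values")
    return table


@dataclass(frozen=True)
class BRTConfig:
    """Boosting hyper-parameters.

    Defaults mirror common BRT practice for this kind of analysis: deep
    enough trees for three-way interactions, slow shrinkage, stochastic
    bagging, tree count picked by 10-fold CV with a hard cap.
    """

    tree_complexity: int = 3
    learning_rate: float = 0.01
    max_trees: int = 10_000
    cv_folds: int = 10
    bag_fraction: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.tree_complexity < 1:
            raise ValidationError("tree_complexity must be >= 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValidationError("learning_rate must be in (0, 1]")
        if self.max_trees < 1:
            raise ValidationError("max_trees must be >= 1")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if not (0.0 < self.bag_fraction <= 1.0):
            raise ValidationError("bag_fraction must be in (0, 1]")


class DriverModel:
    """BRT model of the scaling exponent on driver features.

    Parameters
    ----------
    table : pandas.DataFrame
        Output of :func:`build_driver_table` (or any frame with the feature
        columns and a response column). At least 10 rows and at least
        ``cv_folds`` rows; response must not be constant.
    config : BRTConfig
    feature_columns, response_column :
        Override the default ten-feature layout.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        config: BRTConfig | None = None,
        feature_columns: Sequence[str] | None = None,
        response_column: str = RESPONSE_COLUMN,
    ):
        self.config = config or BRTConfig()
        self.config.validate()
        self.feature_columns = list(feature_columns) if feature_columns else [
            c for c in FEATURE_NAMES if c in table.columns
        ]
        if not self.feature_columns:
            raise ValidationError("no feature columns found in driver table")
        missing = [c for c in (*self.feature_columns, response_column) if c not in table.columns]
        if missing:
            raise ValidationError(f"driver table missing columns: {missing}")
        if len(table) < 10:
            raise ValidationError(f"need >= 10 rows to fit a BRT, got {len(table)}")
        if len(table) < self.config.cv_folds:
            raise ValidationError(
                f"{len(table)} rows cannot support {self.config.cv_folds}-fold CV"
            )
        y = table[response_column].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValidationError("response contains non-finite values")
        if np.ptp(y) == 0.0:
            raise ValidationError("response is constant; no structure to fit")
        self.table = table.reset_index(drop=True)
        self.response_column = response_column
        self.X = self.table[self.feature_columns].to_numpy(dtype=float)
        self.y = y

    def _estimator(self, n_trees: int) -> GradientBoostingRegressor:
        c = self.config
        return GradientBoostingRegressor(
            loss="squared_error",
            n_estimators=n_trees,
            learning_rate=c.learning_rate,
            max_depth=c.tree_complexity,
            subsample=c.bag_fraction,
            random_state=c.seed,
        )

    def fit(self) -> "DriverResults":
        c = self.config
        kf = KFold(n_splits=c.cv_folds, shuffle=True, random_state=c.seed)
        cv_sse = np.zeros(c.max_trees)
        n_val = 0
        for train_idx, val_idx in kf.split(self.X):
            est = self._estimator(c.max_trees).fit(self.X[train_idx], self.y[train_idx])
            y_val = self.y[val_idx]
            n_val += len(val_idx)
            for stage, pred in enumerate(est.staged_predict(self.X[val_idx])):
                cv_sse[stage] += float(np.sum((pred - y_val) ** 2))
        cv_curve = cv_sse / n_val
        n_best = int(np.argmin(cv_curve)) + 1

        final = self._estimator(n_best).fit(self.X, self.y)
        imp = np.asarray(final.feature_importances_, dtype=float)
        total = imp.sum()
        influences = pd.Series(
            100.0 * imp / total if total > 0 else np.full_like(imp, 100.0 / len(imp)),
            index=self.feature_columns,
        )
        return DriverResults(
            influences=influences,
            n_trees_used=n_best,
            cv_curve=cv_curve,
            model=self,
            estimator=final,
        )


@dataclass(frozen=True)
class DriverResults:
    """Fitted BRT with influence percentages and profile access."""

    influences: pd.Series = field(repr=False)
    n_trees_used: int = 0
    cv_curve: np.ndarray = field(default=None, repr=False)
    model: DriverModel = field(default=None, repr=False, compare=False)
    estimator: GradientBoostingRegressor = field(default=None, repr=False, compare=False)

    def relative_influence(self) -> pd.DataFrame:
        """Ordered (feature, percentage, rank); ties broken by feature name."""
        order = sorted(self.influences.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            [{"feature": f, "percentage": p, "rank": i + 1} for i, (f, p) in enumerate(order)]
        )

    def marginal_profile(
        self, feature: str, grid_size: int = 100, kind: str = "at_means"
    ) -> pd.DataFrame:
        """Prediction along one feature's observed range.

        ``kind="at_means"`` pins every other feature at its mean (the
        ceteris-paribus reading of a marginal effect); ``kind="average"``
        averages predictions over the observed rows instead (partial
        dependence). Grid endpoints equal the observed min/max.
        """
        cols = self.model.feature_columns
        if feature not in cols:
            raise ValidationError(f"unknown feature {feature!r}; have {cols}")
        if grid_size < 2:
            raise ValidationError("grid_size must be >= 2")
        j = cols.index(feature)
        X = self.model.X
        grid = np.linspace(X[:, j].min(), X[:, j].max(), grid_size)
        if kind == "at_means":
            base = np.tile(X.mean(axis=0), (grid_size, 1))
            base[:, j] = grid
            pred = self.estimator.predict(base)
        elif kind == "average":
            pred = np.empty(grid_size)
            work = X.copy()
            for g, value in enumerate(grid):
                work[:, j] = value
                pred[g] = float(self.estimator.predict(work).mean())
        else:
            raise ValidationError(f"unknown profile kind {kind!r}")
        return pd.DataFrame({"feature": feature, "grid": grid, "prediction": pred})

    def profiles(self, grid_size: int = 100, kind: str = "at_means") -> pd.DataFrame:
        """Long-format profiles for every feature."""
        return pd.concat(
            [self.marginal_profile(f, grid_size, kind) for f in self.model.feature_columns],
            ignore_index=True,
        )

    def plot_profiles(self, features: Sequence[str] | None = None, grid_size: int = 100,
                      kind: str = "at_means", ncols: int = 3):
        """Small-multiple marginal-effect curves (one panel per feature)."""
        import matplotlib.pyplot as plt

        features = list(features) if features else self.model.feature_columns
        nrows = -(-len(features) // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
        for ax, feat in zip(axes.ravel(), features):
            prof = self.marginal_profile(feat, grid_size=grid_size, kind=kind)
            ax.plot(prof["grid"], prof["prediction"])
            ax.set_title(f"{feat} ({self.influences[feat]:.1f}%)", fontsize=9)
        for ax in axes.ravel()[len(features):]:
            ax.set_visible(False)
        fig.tight_layout()
        return fig

    def summary(self) -> str:
        lines = [
            "Boosted regression tree fit",
            f"  trees used (CV-selected) : {self.n_trees_used}",
            f"  tree complexity          : {self.model.config.tree_complexity}",
            f"  learning rate            : {self.model.config.learning_rate}",
            "  relative influence (%):",
        ]
        for row in self.relative_influence().itertuples():
            lines.append(f"    {row.rank:>2}. {row.feature:<24s} {row.percentage:6.2f}")
        return "\n".join(lines)


# -- functional wrappers ----------------------------------------------------

def fit_brt(table: pd.DataFrame, config: BRTConfig | None = None, **kwargs) -> DriverResults:
    return DriverModel(table, config=config, **kwargs).fit()


def relative_influence(result: DriverResults) -> pd.DataFrame:
    return result.relative_influence()


def marginal_profile(result: DriverResults, feature: str, grid_size: int = 100,
                     kind: str = "at_means") -> pd.DataFrame:
    return result.marginal_profile(feature, grid_size=grid_size, kind=kind)
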