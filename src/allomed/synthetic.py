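"""Synthetic city-panel generator.

The analysis pipeline expects yearbook-style panels: 41 prefecture-level
cities observed 2000-2022, each with a permanent resident population (PRP)
and three raw medical & healthcare (M&H) supply indicators (institutions,
hospital beds, doctors), optionally with the raw components of ten
socio-economic driver ratios. No such dataset is deposited anywhere, so this
module generates panels with the exact statistical structure the estimators
assume:

* resources tied to population through a power law ``M = a * P**b`` with
  either a per-year exponent schedule (cross-sectional "vertical" analysis)
  or a per-city schedule (time-series "horizontal" analysis);
* multiplicative log-normal noise (additive on the natural-log scale, the
  scale on which the estimator works);
* heterogeneous, strictly positive population trajectories;
* driver covariates with configurable monotone effects on the per-city
  exponent, returned together with the ground truth for recovery tests.

A packaged fixture of 23 printed annual scaling exponents (2000-2022, with
goodness of fit and typology label) anchors exact-recovery tests: a
noise-free panel generated from the fixture schedule must reproduce every
exponent to numerical precision downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .panel import INDICATOR_COLUMNS, PanelDataset

__all__ = [
    "PopulationSpec",
    "DriverSpec",
    "SyntheticConfig",
    "FixtureEntry",
    "table2_fixture",
    "generate_vertical_panel",
    "generate_horizontal_panel",
    "generate_driver_panel",
    "DRIVER_NAMES",
    "RAW_COMPONENT_COLUMNS",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Distribution of city population trajectories.

    Initial populations are log-normal by default (log-mean ln 4e6, log-sd
    0.6 — plausible for prefecture cities in a coastal urban agglomeration)
    or log-uniform between ``10**log10_min`` and ``10**log10_max``. Each city
    gets a geometric annual growth rate drawn once from
    ``Normal(growth_mean, growth_sd)``, plus an annual log-scale jitter so
    trajectories are non-constant in log (the slope stays identified).
    """

    distribution: str = "lognormal"  # "lognormal" | "loguniform"
    log_mean: float = math.log(4.0e6)
    log_sd: float = 0.6
    log10_min: float = 5.5
    log10_max: float = 7.5
    growth_mean: float = 0.005
    growth_sd: float = 0.01
    jitter_sd: float = 0.02

    def validate(self) -> None:
        if self.distribution not in ("lognormal", "loguniform"):
            raise ValidationError(f"unknown population distribution {self.distribution!r}")
        if self.log_sd < 0 or self.growth_sd < 0 or self.jitter_sd < 0:
            raise ValidationError("population spread parameters must be >= 0")
        if self.distribution == "loguniform" and self.log10_max <= self.log10_min:
            raise ValidationError("loguniform requires log10_max > log10_min")


#: The ten driver ratios, in canonical order, with (mean, sd) of the
#: per-city latent value on the ratio's natural scale. Units: per-capita GDP
#: yuan/person; density persons/km^2; everything else percent.
DRIVER_NAMES: dict[str, tuple[float, float]] = {
    "per_capita_gdp": (60_000.0, 25_000.0),
    "tertiary_share": (45.0, 8.0),
    "fiscal_ratio": (60.0, 15.0),
    "medical_investment": (7.0, 2.0),
    "urbanization_rate": (65.0, 12.0),
    "population_attraction": (100.0, 15.0),
    "population_density": (600.0, 300.0),
    "income_ratio": (200.0, 30.0),
    "medical_consumption": (7.0, 2.0),
    "aging_rate": (14.0, 4.0),
}

#: Raw yearbook-style component columns emitted by the driver generator,
#: from which the ten ratios are reconstructed downstream.
RAW_COMPONENT_COLUMNS = (
    "gdp",
    "tertiary_value_added",
    "fiscal_revenue",
    "fiscal_expenditure",
    "gov_mh_expenditure",
    "urban_population",
    "registered_population",
    "admin_area_km2",
    "urban_income",
    "rural_income",
    "household_mh_expenditure",
    "living_expenses",
    "pop_aged_65plus",
)


@dataclass(frozen=True)
class DriverSpec:
    """Monotone driver effects on the per-city scaling exponent.

    ``effects`` maps driver names (keys of :data:`DRIVER_NAMES`) to the
    change in the exponent per one standard deviation of the driver; drivers
    not named are pure noise. ``noise_sd`` is nuisance noise on the exponent
    itself; ``baseline`` is the exponent of a city with all drivers at their
    means.
    """

    effects: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.05
    baseline: float = 1.0

    def validate(self) -> None:
        unknown = [k for k in self.effects if k not in DRIVER_NAMES]
        if unknown:
            raise ValidationError(f"unknown driver(s) in effect spec: {unknown}")
        if self.noise_sd < 0:
            raise ValidationError("driver noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic panel.

    Exactly one of ``exponents_by_year`` / ``exponents_by_city`` may be set;
    the vertical generator requires the former, the horizontal and driver
    generators the latter (the driver generator derives its own per-city
    exponents and needs neither). ``noise_sd`` is the standard deviation of
    the additive log-scale noise on resource totals; ``intercept`` is the
    power-law scale factor ``a``. ``indicator_shares`` split each total into
    institutions/beds/doctors and must be positive and sum to 1.
    """

    n_cities: int = 41
    year_start: int = 2000
    year_end: int = 2022
    exponents_by_year: Mapping[int, float] | None = None
    exponents_by_city: Sequence[float] | None = None
    intercept: float = 1.0
    noise_sd: float = 0.05
    indicator_noise_sd: float = 0.0
    population: PopulationSpec = field(default_factory=PopulationSpec)
    indicator_shares: tuple[float, float, float] = (0.30, 0.35, 0.35)
    drivers: DriverSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_cities < 3:
            raise ValidationError("n_cities must be >= 3 (a cross-sectional slope needs >= 3 points)")
        if self.year_end < self.year_start:
            raise ValidationError("year_end must be >= year_start")
        if self.noise_sd < 0 or self.indicator_noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.intercept <= 0:
            raise ValidationError("intercept a must be > 0")
        shares = np.asarray(self.indicator_shares, dtype=float)
        if len(shares) != 3 or (shares <= 0).any() or abs(shares.sum() - 1.0) > 1e-9:
            raise ValidationError("indicator_shares must be three positive values summing to 1")
        if self.exponents_by_year is not None and self.exponents_by_city is not None:
            raise ValidationError("set only one of exponents_by_year / exponents_by_city")
        self.population.validate()
        if self.drivers is not None:
            self.drivers.validate()

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))


class FixtureEntry(NamedTuple):
    exponent: float
    r_squared: float
    label: str


def table2_fixture() -> dict[int, FixtureEntry]:
    """Packaged annual scaling-exponent fixture, year -> entry.

    Twenty-three (year, exponent, goodness of fit, typology label) rows for
    2000-2022, as printed in the source study of the Yangtze River Delta.
    """
    with resources.files("allomed.data").joinpath("annual_exponents.csv").open("r") as fh:
        frame = pd.read_csv(fh)
    return {
        int(r.year): FixtureEntry(float(r.exponent), float(r.r_squared), str(r.label))
        for r in frame.itertuples()
    }


# ---------------------------------------------------------------------------
# internal draws


def _population_paths(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """ln P, shape (n_cities, n_years)."""
    spec = config.population
    n, t = config.n_cities, len(config.years)
    if spec.distribution == "lognormal":
        ln_p0 = rng.normal(spec.log_mean, spec.log_sd, size=n)
    else:
        ln_p0 = rng.uniform(spec.log10_min, spec.log10_max, size=n) * math.log(10.0)
    growth = rng.normal(spec.growth_mean, spec.growth_sd, size=n)
    jitter = rng.normal(0.0, spec.jitter_sd, size=(n, t - 1)) if t > 1 else np.zeros((n, 0))
    steps = np.log1p(np.clip(growth, -0.5, None))[:, None] + jitter
    return ln_p0[:, None] + np.concatenate([np.zeros((n, 1)), np.cumsum(steps, axis=1)], axis=1)


def _assemble(config: SyntheticConfig, ln_p: np.ndarray, ln_m: np.ndarray,
              rng: np.random.Generator,
              extra: dict[str, np.ndarray] | None = None) -> PanelDataset:
    """Build the long-format panel from log population / log resource grids.

    The total is split into institutions/beds/doctors by the configured
    shares; optional indicator-level log-normal noise (off by default)
    perturbs each indicator after the split.
    """
    years = np.asarray(config.years)
    n, t = ln_p.shape
    city_ids = [f"C{i + 1:02d}" for i in range(n)]
    shares = np.asarray(config.indicator_shares, dtype=float)
    total = np.exp(ln_m)
    data = {
        "city_id": np.repeat(city_ids, t),
        "year": np.tile(years, n),
        "prp": np.exp(ln_p).ravel(),
    }
    for share, col in zip(shares, INDICATOR_COLUMNS):
        part = share * total
        if config.indicator_noise_sd > 0:
            part = part * np.exp(rng.normal(0.0, config.indicator_noise_sd, size=part.shape))
        data[col] = part.ravel()
    if extra:
        for col, grid in extra.items():
            data[col] = np.asarray(grid).ravel()
    return PanelDataset.from_frame(pd.DataFrame(data))


# ---------------------------------------------------------------------------
# generators


def generate_vertical_panel(config: SyntheticConfig) -> PanelDataset:
    """Panel whose yearly cross-sections obey ``ln M = ln a + b_t ln P + eps``.

    Requires a per-year exponent schedule covering every year of the config
    range. With ``noise_sd = 0`` the power law holds to numerical precision,
    so a per-year log-log OLS downstream recovers each ``b_t`` exactly.
    """
    config.validate()
    if config.exponents_by_year is None:
        raise ValidationError("generate_vertical_panel needs exponents_by_year")
    missing = [y for y in config.years if y not in config.exponents_by_year]
    if missing:
        raise ValidationError(f"exponent schedule missing years: {missing}")

    rng = np.random.default_rng(config.seed)
    ln_p = _population_paths(config, rng)
    b_t = np.asarray([config.exponents_by_year[y] for y in config.years], dtype=float)
    eps = rng.normal(0.0, config.noise_sd, size=ln_p.shape) if config.noise_sd > 0 else 0.0
    ln_m = math.log(config.intercept) + b_t[None, :] * ln_p + eps
    return _assemble(config, ln_p, ln_m, rng)


def generate_horizontal_panel(config: SyntheticConfig) -> PanelDataset:
    """Panel where each city's time series obeys ``ln M = ln a + b_i ln P + eps``.

    Requires per-city exponents (one per city) and at least 3 years. A city
    whose drawn population series is constant on the log scale would leave
    the slope unidentified; such a draw is rejected with an error rather
    than silently passed downstream.
    """
    config.validate()
    if config.exponents_by_city is None:
        raise ValidationError("generate_horizontal_panel needs exponents_by_city")
    b_i = np.asarray(config.exponents_by_city, dtype=float)
    if len(b_i) != config.n_cities:
        raise ValidationError(
            f"exponents_by_city has {len(b_i)} entries for {config.n_cities} cities"
        )
    if len(config.years) < 3:
        raise ValidationError("horizontal generation needs >= 3 years")

    rng = np.random.default_rng(config.seed)
    ln_p = _population_paths(config, rng)
    constant = np.ptp(ln_p, axis=1) <= 1e-12
    if constant.any():
        raise ValidationError(
            f"drawn population series constant in log for cities {np.where(constant)[0].tolist()}; "
            "increase growth_sd or jitter_sd"
        )
    eps = rng.normal(0.0, config.noise_sd, size=ln_p.shape) if config.noise_sd > 0 else 0.0
    ln_m = math.log(config.intercept) + b_i[:, None] * ln_p + eps
    return _assemble(config, ln_p, ln_m, rng)


def generate_driver_panel(config: SyntheticConfig) -> tuple[PanelDataset, pd.DataFrame]:
    """Horizontal panel plus driver covariates and ground-truth exponents.

    Each city draws a latent value for each of the ten driver ratios; its
    scaling exponent is ``baseline + sum_k effect_k * z_ik + noise`` where
    ``z_ik`` is the driver standardized by its nominal mean/sd (a linear,
    hence monotone, link). The panel carries raw yearbook-style component
    columns from which the ratios are reconstructed downstream; the second
    return value is the ground truth (city_id, the ten ratio values,
    true_exponent) for recovery tests.
    """
    config.validate()
    if config.exponents_by_city is not None or config.exponents_by_year is not None:
        raise ValidationError("generate_driver_panel derives exponents; leave schedules unset")
    drivers = config.drivers if config.drivers is not None else DriverSpec()
    drivers.validate()
    if len(config.years) < 3:
        raise ValidationError("driver panel generation needs >= 3 years")

    rng = np.random.default_rng(config.seed)
    n = config.n_cities

    ratios: dict[str, np.ndarray] = {}
    z: dict[str, np.ndarray] = {}
    for name, (mean, sd) in DRIVER_NAMES.items():
        draw = rng.normal(mean, sd, size=n)
        draw = np.clip(draw, 0.05 * mean, None)  # ratios are positive quantities
        ratios[name] = draw
        z[name] = (draw - mean) / sd

    b_i = np.full(n, drivers.baseline, dtype=float)
    for name, effect in drivers.effects.items():
        b_i += effect * z[name]
    if drivers.noise_sd > 0:
        b_i += rng.normal(0.0, drivers.noise_sd, size=n)

    ln_p = _population_paths(config, rng)
    constant = np.ptp(ln_p, axis=1) <= 1e-12
    if constant.any():
        raise ValidationError(
            f"drawn population series constant in log for cities {np.where(constant)[0].tolist()}"
        )
    eps = rng.normal(0.0, config.noise_sd, size=ln_p.shape) if config.noise_sd > 0 else 0.0
    ln_m = math.log(config.intercept) + b_i[:, None] * ln_p + eps

    # Raw components consistent with each city's ratio values; quantities that
    # scale with city size track the population path.
    prp = np.exp(ln_p)  # (n, t)
    col = lambda v: np.repeat(np.asarray(v)[:, None], ln_p.shape[1], axis=1)
    gdp = col(ratios["per_capita_gdp"]) * prp
    fiscal_expenditure = 0.20 * gdp
    rural_income = col(0.30 * ratios["per_capita_gdp"])
    urban_income = col(ratios["income_ratio"] / 100.0) * rural_income
    living_expenses = 0.60 * urban_income
    extra = {
        "gdp": gdp,
        "tertiary_value_added": col(ratios["tertiary_share"] / 100.0) * gdp,
        "fiscal_revenue": col(ratios["fiscal_ratio"] / 100.0) * fiscal_expenditure,
        "fiscal_expenditure": fiscal_expenditure,
        "gov_mh_expenditure": col(ratios["medical_investment"] / 100.0) * fiscal_expenditure,
        "urban_population": col(ratios["urbanization_rate"] / 100.0) * prp,
        "registered_population": prp / col(ratios["population_attraction"] / 100.0),
        "admin_area_km2": col(np.exp(ln_p[:, 0]) / ratios["population_density"]) * np.ones_like(prp),
        "urban_income": urban_income,
        "rural_income": rural_income,
        "household_mh_expenditure": col(ratios["medical_consumption"] / 100.0) * living_expenses,
        "living_expenses": living_expenses,
        "pop_aged_65plus": col(ratios["aging_rate"] / 100.0) * prp,
    }
    panel = _assemble(config, ln_p, ln_m, rng, extra=extra)

    truth = pd.DataFrame({"city_id": [f"C{i + 1:02d}" for i in range(n)]})
    for name in DRIVER_NAMES:
        truth[name] = ratios[name]
    truth["true_exponent"] = b_i
    return panel, truth


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different seed (replicate helper)."""
    return replace(config, seed=seed)
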