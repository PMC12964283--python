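"""Scaling-exponent estimation: exact identification, equivariance, stages."""

import math

import numpy as np
import pytest
from scipy import stats

import allomed as am
from allomed.exceptions import ValidationError


def test_identity_power_law_recovered_exactly():
    e = math.e
    res = am.fit_allometry([(e, e), (e**2, e**2), (e**3, e**3)])
    assert res.exponent == pytest.approx(1.0, abs=1e-12)
    assert res.ln_intercept == pytest.approx(0.0, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)


def test_hand_ols_on_collinear_log_points():
    # ln M doubles per decade of P: slope = ln 4 / ln 10
    res = am.fit_allometry(population=[10, 100, 1000], supply=[2, 8, 32])
    assert res.exponent == pytest.approx(math.log(4) / math.log(10), abs=1e-12)
    assert res.r_squared == pytest.approx(1.0, abs=1e-9)


def test_fit_matches_scipy_linregress_on_noisy_data():
    rng = np.random.default_rng(0)
    p = rng.uniform(1e5, 1e7, 41)
    m = 0.5 * p**0.9 * np.exp(rng.normal(0, 0.2, 41))
    res = am.fit_allometry(population=p, supply=m)
    oracle = stats.linregress(np.log(p), np.log(m))
    assert res.exponent == pytest.approx(oracle.slope, abs=1e-10)
    assert res.ln_intercept == pytest.approx(oracle.intercept, abs=1e-10)
    assert res.r_squared == pytest.approx(oracle.rvalue**2, abs=1e-10)


@pytest.mark.parametrize("p,m,match", [
    ([1, 2], [1, 2], ">= 3"),
    ([1, -2, 3], [1, 2, 3], "population"),
    ([1, 2, 3], [1, 0, 3], "supply"),
    ([2, 2, 2], [1, 2, 3], "all equal"),
])
def test_degenerate_inputs_are_rejected(p, m, match):
    with pytest.raises(ValidationError, match=match):
        am.fit_allometry(population=p, supply=m)


def test_population_rescaling_changes_intercept_not_slope():
    rng = np.random.default_rng(1)
    p = rng.uniform(1e5, 1e7, 30)
    m = 2.0 * p**1.1 * np.exp(rng.normal(0, 0.1, 30))
    r1 = am.fit_allometry(population=p, supply=m)
    r2 = am.fit_allometry(population=10.0 * p, supply=m)
    assert r2.exponent == pytest.approx(r1.exponent, abs=1e-10)
    assert r2.r_squared == pytest.approx(r1.r_squared, abs=1e-10)
    assert r2.ln_intercept != pytest.approx(r1.ln_intercept, abs=1e-3)


def test_swapping_axes_inverts_the_exponent_on_noise_free_data():
    p = np.array([1e5, 5e5, 2e6, 9e6])
    m = 0.3 * p**1.7
    forward = am.fit_allometry(population=p, supply=m)
    backward = am.fit_allometry(population=m, supply=p)
    assert backward.exponent == pytest.approx(1.0 / forward.exponent, abs=1e-9)


def test_two_year_generator_roundtrip():
    cfg = am.SyntheticConfig(
        n_cities=10, year_start=2000, year_end=2001,
        exponents_by_year={2000: 0.5, 2001: 2.0}, noise_sd=0.0, seed=6,
    )
    panel = am.generate_vertical_panel(cfg)
    fits = am.vertical_series(panel, am.total_supply_series(panel))
    assert [f.scope.year for f in fits] == [2000, 2001]
    assert fits[0].exponent == pytest.approx(0.5, abs=1e-9)
    assert fits[1].exponent == pytest.approx(2.0, abs=1e-9)


def test_horizontal_fits_recover_generator_exponents_exactly(mixed_horizontal_panel):
    panel, b_true = mixed_horizontal_panel
    fits, exclusions = am.horizontal_fits(panel, am.total_supply_series(panel), (2000, 2022))
    assert not exclusions
    assert len(fits) == 41
    for i, city in enumerate(sorted(fits)):
        assert fits[city].exponent == pytest.approx(b_true[i], abs=1e-9)


def test_negative_exponent_recovered_and_classified_nag3():
    cfg = am.SyntheticConfig(
        n_cities=3, year_start=2000, year_end=2010,
        exponents_by_city=(-0.3, 1.0, 1.0), noise_sd=0.0, seed=8,
    )
    panel = am.generate_horizontal_panel(cfg)
    fits, _ = am.horizontal_fits(panel, am.total_supply_series(panel), (2000, 2010))
    res = fits["C01"]
    assert res.exponent == pytest.approx(-0.3, abs=1e-9)
    assert am.classify_exponent(res.exponent).label == "NAG3"


def test_city_with_constant_population_lands_in_exclusion_list():
    cfg = am.SyntheticConfig(
        n_cities=3, year_start=2000, year_end=2010,
        exponents_by_city=(1.0, 1.0, 1.0), noise_sd=0.0, seed=9,
    )
    panel = am.generate_horizontal_panel(cfg)
    frame = panel.frame.copy()
    mask = frame["city_id"] == "C01"
    frame.loc[mask, "prp"] = 1_000_000.0
    broken = am.PanelDataset.from_frame(frame)
    fits, exclusions = am.horizontal_fits(broken, am.total_supply_series(broken), (2000, 2010))
    assert "C01" not in fits
    assert any(e["city_id"] == "C01" for e in exclusions)


def test_slope_estimator_is_unbiased_at_moderate_noise():
    """noise_sd 0.1, n = 41: mean slope over 200 replicates within MC error of truth."""
    b_true = 1.0
    estimates = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        p = np.exp(rng.normal(np.log(4e6), 0.6, 41))
        m = p**b_true * np.exp(rng.normal(0, 0.1, 41))
        estimates.append(am.fit_allometry(population=p, supply=m).exponent)
    estimates = np.asarray(estimates)
    sem = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - b_true) <= 4 * sem


def test_spread_of_slope_estimates_shrinks_with_sample_size():
    def spread(n):
        ests = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            p = np.exp(rng.normal(np.log(4e6), 0.6, n))
            m = p * np.exp(rng.normal(0, 0.1, n))
            ests.append(am.fit_allometry(population=p, supply=m).exponent)
        return np.std(ests)

    assert spread(100) < spread(10)


def test_stage_partition_of_fixture_series(noise_free_vertical_panel):
    fits = am.vertical_series(noise_free_vertical_panel,
                              am.total_supply_series(noise_free_vertical_panel))
    part = am.stage_partition(fits)
    assert part.ranges == (
        (2000, 2003, "PRP expansion"),
        (2004, 2014, "basic coordination"),
        (2015, 2022, "M&H expansion"),
    )


def test_stage_partition_merging_rules():
    def fake(year, b):
        p = np.array([1e5, 1e6, 1e7])
        return am.fit_allometry(population=p, supply=p**b,
                                scope=am.FitScope(mode="vertical", year=year))

    constant = am.stage_partition([fake(2000 + i, 0.9) for i in range(5)])
    assert constant.ranges == ((2000, 2004, "basic coordination"),)

    zigzag = am.stage_partition([fake(2000, 0.84), fake(2001, 0.86), fake(2002, 0.84)])
    assert [r[2] for r in zigzag.ranges] == [
        "PRP expansion", "basic coordination", "PRP expansion",
    ]
    assert all(r[0] == r[1] for r in zigzag.ranges)
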