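"""Driver table construction and BRT behaviour (influence, profiles)."""

import numpy as np
import pandas as pd
import pytest

import allomed as am
from allomed.drivers import FEATURE_NAMES, RESPONSE_COLUMN
from allomed.exceptions import ValidationError

FAST_BRT = am.BRTConfig(tree_complexity=3, learning_rate=0.05, max_trees=300,
                        cv_folds=3, bag_fraction=0.75, seed=0)


def _driver_setup(seed=0, effects=None, noise_sd=0.05, n_cities=41):
    spec = am.DriverSpec(effects=effects or {}, noise_sd=noise_sd)
    cfg = am.SyntheticConfig(n_cities=n_cities, year_start=2000, year_end=2010,
                             drivers=spec, noise_sd=0.0, seed=seed)
    return am.generate_driver_panel(cfg)


def _truth_as_table(truth: pd.DataFrame) -> pd.DataFrame:
    return truth.rename(columns={"true_exponent": RESPONSE_COLUMN})


def test_build_driver_table_computes_table_ratios():
    panel, truth = _driver_setup(seed=1)
    fits, _ = am.horizontal_fits(panel, am.total_supply_series(panel), (2000, 2010))
    table = am.build_driver_table(panel, fits, (2000, 2010))
    assert list(table["city_id"]) == sorted(fits)
    assert set(FEATURE_NAMES).issubset(table.columns)

    frame = panel.frame
    row = frame.iloc[0]
    # per-capita GDP is GDP over PRP; urbanization is urban pop share in %
    assert row["gdp"] / row["prp"] == pytest.approx(
        truth.loc[truth.city_id == row["city_id"], "per_capita_gdp"].iloc[0], rel=1e-9)
    city_window = frame[(frame.city_id == row["city_id"])]
    expect_urb = (100 * city_window["urban_population"] / city_window["prp"]).mean()
    got = table.loc[table.city_id == row["city_id"], "urbanization_rate"].iloc[0]
    assert got == pytest.approx(expect_urb, rel=1e-9)
    # response is the period's horizontal exponent
    for rec in table.itertuples():
        assert getattr(rec, RESPONSE_COLUMN) == pytest.approx(fits[rec.city_id].exponent)


def test_period_mean_feature_is_mean_of_annual_ratios():
    panel, _ = _driver_setup(seed=2)
    frame = panel.frame.copy()
    # force a known two-year ratio pattern for one city
    mask = (frame.city_id == "C01") & frame.year.isin([2000, 2001])
    frame.loc[mask & (frame.year == 2000), "gov_mh_expenditure"] = \
        0.10 * frame.loc[mask & (frame.year == 2000), "fiscal_expenditure"]
    frame.loc[mask & (frame.year == 2001), "gov_mh_expenditure"] = \
        0.20 * frame.loc[mask & (frame.year == 2001), "fiscal_expenditure"]
    panel2 = am.PanelDataset.from_frame(frame)
    fits, _ = am.horizontal_fits(panel2, am.total_supply_series(panel2), (2000, 2001 + 2))
    table = am.build_driver_table(panel2.subset_years(2000, 2001), fits, (2000, 2001))
    got = table.loc[table.city_id == "C01", "medical_investment"].iloc[0]
    assert got == pytest.approx(15.0, rel=1e-9)


def test_missing_component_error_names_the_factor():
    panel, _ = _driver_setup(seed=3)
    frame = panel.frame.drop(columns=["registered_population"])
    broken = am.PanelDataset.from_frame(frame)
    fits, _ = am.horizontal_fits(broken, am.total_supply_series(broken), (2000, 2010))
    with pytest.raises(ValidationError, match="population attraction"):
        am.build_driver_table(broken, fits, (2000, 2010))


def test_constant_response_is_rejected():
    _, truth = _driver_setup(seed=4, noise_sd=0.0)  # no effects, no noise
    table = _truth_as_table(truth)
    with pytest.raises(ValidationError, match="constant"):
        am.fit_brt(table, FAST_BRT)


def test_too_few_rows_rejected():
    _, truth = _driver_setup(seed=5, n_cities=8, effects={"aging_rate": 0.2})
    with pytest.raises(ValidationError, match=">= 10 rows"):
        am.fit_brt(_truth_as_table(truth), FAST_BRT)


def test_influences_sum_to_100_and_fit_is_deterministic():
    _, truth = _driver_setup(seed=6, effects={"medical_consumption": 0.3})
    table = _truth_as_table(truth)
    r1 = am.fit_brt(table, FAST_BRT)
    r2 = am.fit_brt(table, FAST_BRT)
    assert abs(r1.influences.sum() - 100.0) <= 1e-6
    pd.testing.assert_series_equal(r1.influences, r2.influences)
    assert r1.n_trees_used == r2.n_trees_used

    ri = r1.relative_influence()
    assert list(ri["rank"]) == list(range(1, len(ri) + 1))
    assert ri["percentage"].is_monotonic_decreasing


def test_rank_ties_break_lexicographically():
    res = am.DriverResults(
        influences=pd.Series({"b_feat": 10.0, "a_feat": 10.0, "c_feat": 80.0}),
        n_trees_used=1,
    )
    ri = res.relative_influence()
    assert list(ri["feature"]) == ["c_feat", "a_feat", "b_feat"]


def test_single_strong_driver_tops_influence_ranking():
    _, truth = _driver_setup(seed=7, effects={"per_capita_gdp": 0.4}, noise_sd=0.03)
    res = am.fit_brt(_truth_as_table(truth), FAST_BRT)
    assert res.relative_influence().iloc[0]["feature"] == "per_capita_gdp"


def test_profile_grid_spans_observed_range_and_flat_for_unused_feature():
    rng = np.random.default_rng(8)
    table = pd.DataFrame({
        "x_active": rng.uniform(0, 10, 40),
        "x_unused": np.full(40, 0.5),  # constant: no tree can ever split on it
    })
    table[RESPONSE_COLUMN] = 2.0 * table["x_active"]
    res = am.fit_brt(table, FAST_BRT, feature_columns=["x_active", "x_unused"])
    assert res.influences["x_unused"] == 0.0
    prof = res.marginal_profile("x_unused", grid_size=25)
    assert prof["prediction"].nunique() == 1  # never split on -> flat
    active = res.marginal_profile("x_active", grid_size=25)
    assert active["grid"].iloc[0] == pytest.approx(table["x_active"].min())
    assert active["grid"].iloc[-1] == pytest.approx(table["x_active"].max())

    with pytest.raises(ValidationError, match="unknown feature"):
        res.marginal_profile("nope")


def test_profile_of_monotone_response_is_nearly_monotone():
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 10, 60)
    table = pd.DataFrame({"x": x, "z": rng.uniform(0, 1, 60)})
    table[RESPONSE_COLUMN] = np.sqrt(x)
    cfg = am.BRTConfig(learning_rate=0.1, max_trees=400, cv_folds=3, seed=9)
    res = am.fit_brt(table, cfg, feature_columns=["x", "z"])
    pred = res.marginal_profile("x", grid_size=50)["prediction"].to_numpy()
    drops = np.clip(np.diff(pred), None, 0.0)
    span = pred.max() - pred.min()
    assert span > 0
    assert -drops.sum() <= 0.05 * span  # non-decreasing up to boosting wiggle


def test_shifting_a_non_target_feature_leaves_the_target_grid_fixed():
    _, truth = _driver_setup(seed=10, effects={"aging_rate": 0.3})
    table = _truth_as_table(truth)
    res1 = am.fit_brt(table, FAST_BRT)
    shifted = table.copy()
    shifted["per_capita_gdp"] += 5_000.0
    res2 = am.fit_brt(shifted, FAST_BRT)
    g1 = res1.marginal_profile("aging_rate", 20)["grid"]
    g2 = res2.marginal_profile("aging_rate", 20)["grid"]
    pd.testing.assert_series_equal(g1, g2)


def test_average_partial_dependence_variant_runs():
    _, truth = _driver_setup(seed=11, effects={"aging_rate": 0.3})
    res = am.fit_brt(_truth_as_table(truth), FAST_BRT)
    prof = res.marginal_profile("aging_rate", grid_size=10, kind="average")
    assert len(prof) == 10 and prof["prediction"].notna().all()
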