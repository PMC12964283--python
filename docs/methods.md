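# Methods

## Model

The package treats a city system's medical & healthcare (M&H) resource
supply as allometrically coupled to its permanent resident population
(PRP): `M = a · P^b`, fitted as `ln M = ln a + b ln P` by ordinary least
squares on natural logs (statsmodels OLS behind `AllometricModel`). The
estimator assumes multiplicative (log-normal) noise on supply, strictly
positive `P` and `M`, and at least three observations with non-degenerate
variation in `ln P`; violations raise errors naming the offending records
rather than silently dropping rows. No standard errors or confidence
intervals for `b` are reported — the downstream typology consumes the point
estimate only.

Two estimation scopes are exposed. **Vertical** fits one cross-city
regression per calendar year; **horizontal** fits one per-city regression
over the years of a period window (defaults 2000–2010 and 2011–2022). A
terminological caveat: in parts of the urban-scaling literature the verbal
definitions of "vertical" and "horizontal" read the opposite way from how
the corresponding results tables are actually constructed (one exponent
per year across cities; one type per city per period). This package names
the modes after the construction, which is the only reading consistent
with a per-year exponent series and a per-city typology, and says so here
rather than guessing at intent.

### Stage partition and typology

The vertical series is labelled year by year — `b < 0.85` "PRP expansion",
`0.85 ≤ b < 1` "basic coordination", `b ≥ 1` "M&H expansion" — and
consecutive equal labels merge into contiguous stages. Horizontal
exponents map into six classes on half-open, lower-inclusive intervals:
NAG3 `(−∞, 0)`, NAG2 `[0, 0.5)`, NAG1 `[0.5, 0.85)`, PAG1 `[0.85, 1)`,
PAG2 `[1, 3)`, PAG3 `[3, ∞)`. Classes carry ordinal ranks NAG3 = 0 …
PAG3 = 5, ordered by the b-interval; between-period changes are "upgraded"
/ "downgraded" when the rank moves and otherwise decided by the sign of
Δb with a 1e-9 stability tolerance — the within-level refinement is a
declared interpretation, since "improvement within a level" has no
standard numeric definition. Percentage shares are rounded half-up to two
decimals (so 24 of 41 prints as 58.54).

## Composite supply index

The three raw indicators are combined by range normalization over the
pooled city × year panel, entropy weighting (`p_ij = Z_ij / Σ_i Z_ij`,
`e_j = −(1/ln n) Σ p_ij ln p_ij` with `0·ln 0 := 0`,
`w_j ∝ 1 − e_j`), and weighted summation. Pooling is the default because a
single weight triple should describe the whole study window; per-year
weighting exists behind a flag. After normalization an epsilon shift
`(Z + ε)/(1 + ε)` with ε = 1e-4 keeps the composite strictly positive so
it can enter the logarithm; ε is recorded in the output metadata. Whether
the original analyses shifted zeros or dropped them is not documented
anywhere we know of; the shift is this package's declared choice.

One numerical consequence matters for testing: range normalization is
affine, not power-law preserving, so a log-log regression on the
*composite* of a panel generated with exponent `b` does not return `b`
exactly. Exact-recovery checks therefore fit on the raw resource total
(`total_supply_series`), which is proportional to the generated power-law
quantity; the full pipeline defaults to the composite, matching how the
index is meant to be used on real data.

## Driver decomposition (BRT)

The per-city horizontal exponent per period is regressed on ten driver
ratios (features = period means of the annual ratios) with stagewise
gradient boosting: squared-error loss, interaction depth 3, learning rate
0.01, bag fraction 0.75, tree count selected by 10-fold cross-validation
over a staged sequence capped at 10,000 trees, then refit on all rows —
the conventional BRT recipe for ecological regression. scikit-learn's
`GradientBoostingRegressor` supplies the boosting machinery; the CV tree
selection, influence tabulation and profiles are implemented in-package.
Each period gets its own model. Relative influences are the ensemble's
normalized split-improvement shares (summing to 100; rank ties broken
lexicographically by feature name). Marginal-effect profiles evaluate the
model along one feature's observed range with all other features pinned at
their means — a ceteris-paribus curve, not averaged partial dependence,
which is available via `kind="average"`. Given the same table and seed the
whole fit is deterministic.

Tests and the acceptance checks run the BRT at a reduced scale
(max 300–500 trees, learning rate 0.05, 3-fold CV): with 41 cities and one
or two strong simulated drivers, rank recovery is already stable there,
and the checks exercise exactly the same code path as the production
defaults.

## Synthetic data

The generator emulates the study conditions the estimators assume:
41 cities × 23 years (2000–2022) by default. Initial populations are
log-normal (log-mean ln 4×10⁶, log-sd 0.6 — plausible for prefecture-level
cities in a coastal urban agglomeration) or log-uniform on
[10^5.5, 10^7.5]; each city draws a geometric growth rate from
Normal(0.005, 0.01) per year plus a 0.02 log-scale annual jitter so
trajectories are never constant in log. Resource totals follow the power
law with either per-year or per-city exponents and additive log-scale
noise (default sd 0.05), then split into institutions/beds/doctors by
shares (0.30, 0.35, 0.35); optional indicator-level log-normal noise is
off by default. Driver panels draw per-city latent ratio values from
nominal means/sds, set the true exponent as
`baseline + Σ effect_k · z_k + noise` (linear, hence monotone, in each
standardized driver), and emit raw yearbook-style component columns from
which the ten ratios are reconstructed downstream, plus the ground truth
for recovery tests. All randomness flows through one integer seed.

A packaged fixture of 23 printed annual exponents with goodness of fit and
typology labels anchors exact round-trips: noise-free panels generated
from the schedule must reproduce every exponent to ≤ 1e-6 downstream, and
classifying the fixture exponents must reproduce every printed label.

What the generator does *not* emulate — administrative boundary changes,
spatial correlation among neighbouring cities, realistic joint
distributions of the drivers (no public description of them exists), or
serially correlated supply shocks. Passing tests therefore demonstrate
correctness of the estimators and classifiers under the assumed data
model, not robustness to those real-data complications.

One calibration note: with the default slow-growth trajectories, a single
city's 23-year series contains little identifying variation in `ln P`
(spread ≈ 0.04), so per-city slope estimates at noise sd 0.05 carry a
standard error near 0.2. The Monte-Carlo tests assert nominal ±2·SE
coverage under those defaults and tight (±0.15) recovery under a
fast-growing-city scenario (4%/year) where the information content
supports it.

## Jenks natural breaks

Map-ready binning uses exact Fisher–Jenks dynamic programming (O(k n²)
with prefix sums), minimizing total within-class SSE; an exhaustive-search
oracle confirms optimality for small inputs in the tests. Class count
defaults to 5, is configurable, and is used only for export binning, never
inside the statistics.

## Numerical choices and degenerate inputs

- Natural logarithms throughout.
- Minimum 3 observations per scaling fit; horizontal fits surface excluded
  cities in a machine-readable exclusion list.
- Constant indicator columns, constant BRT responses, constant population
  series and non-finite exponents are rejected with named errors.
- R² is clamped to [0, 1] (collinear fits can return 1 + ε) and set to 0
  for a constant response.
- Share rounding: decimal half-up at 2 places.
- Pipeline outputs carry no timestamps; identical configs produce
  byte-identical result bundles.

## Problem sizes

The test suite and the acceptance script use the study-scale panel
(41 cities × 23 years) for all deterministic checks, 200 replicates for
Monte-Carlo estimator properties, 50 seeded replicates for BRT rank
recovery, and n ≤ 12 inputs for the Jenks oracle comparison.

## Known limitations

- The entropy weights printed for the original yearbook panel
  (0.2774 / 0.3581 / 0.3645) cannot be reproduced because those data are
  not deposited; the weights enter tests only as format/contract examples.
- Per-city exponents estimated from slow-moving populations are noisy
  (see the calibration note above); interpreting a single city's class
  should account for that uncertainty even though the method reports none.
- BRT influences are associational; no causal reading is supported, and no
  interaction statistics or SHAP-style attributions are provided.
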