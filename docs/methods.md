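# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `mobishift`, and what its synthetic-data tests do
and do not establish about real mobility data.

## The mobility-change metric

Per origin region `i`, mobility change between a test window and a baseline
window is `λ_mob(i) = ln(A_i / B_i)` with `A_i` (respectively `B_i`) the
mean daily outbound pass-through visit count, summed over non-excluded
destination zones and divided by the origin's sample coverage in the same
window.  Conventions and their rationale:

* **Natural log.** λ is dimensionless; −0.693 means mobility halved.
* **Exclusion rule.** A destination zone is excluded from an origin's sum
  when the two polygons share *any* point — overlapping interiors or
  touching boundaries, corner contact included.  This is the conservative
  reading of "adjacent and intersecting": it removes every pair in which
  GPS jitter and within-region movement could masquerade as travel.  The
  geometric predicate is evaluated exactly on the polygons (shapely), and a
  brute-force all-pairs oracle confirms it on small grids in the tests.
* **Coverage container.** Coverage is read from the destination zone that
  fully contains the origin (boundary contact allowed, so an origin flush
  against its zone's edge still counts as contained).  Partial overlap is
  never pro-rated: origins without a full container have undefined coverage
  and are omitted.  Disjoint zone interiors guarantee at most one container.
* **Omission, not imputation.** Origins with undefined or zero coverage, or
  zero outflow in either window, are dropped with a reason code
  (`no_coverage`, `zero_coverage`, `zero_outflow_test`,
  `zero_outflow_base`).  No pseudocounts: λ is reported only where it is
  defined.
* **Per-day means vs window totals.** Both numerator and denominator are
  stored as mean counts per day.  Because λ is a ratio of ratios over the
  same two windows, per-day means and window totals give identical values;
  whether coverage is a daily mean or a window total is likewise
  irrelevant to λ.  Per-day means are the stored convention.
* **Invariances** (all property-tested): swapping the windows negates λ;
  jointly rescaling one window's visits and coverage by any factor leaves λ
  unchanged; enlarging the exclusion set can only decrease outflows.

## Stratification

ER and EO scores are cut into **local decile bands**: within each city,
scores are ranked (average rank for ties) and the ranks cut at the 10%,
…, 90% empirical quantiles, so decile 1 is the lowest-scoring tenth.  The
assignment depends only on the score ordering — any strictly increasing
transform of the scores yields identical bands — which matches the ordinal
nature of area-level SES indices.  Fewer than 10 regions per city, or a
fully tied score column, is an error rather than a silent degenerate cut.

Reported summaries: per-decile medians of λ (the input to the trend test),
the joint 10×10 ER×EO grid of cell medians with a companion count grid
(empty cells are reported missing, never interpolated), and letter-value
summaries per decile.  Letter values follow the halved-depth recursion
(`d₁ = (1+n)/2`, `d_{k+1} = (1+⌊d_k⌋)/2`, value = mean of the two bracketing
order statistics from each end); a new level is added only while at least 5
observations lie outside the current letter-value pair, so small groups stop
at the median or fourths.

## Mann–Kendall trend test

The score is `S = Σ_{j>i} sign(x_j − x_i)` over the 10 decile medians; ties
contribute 0.  The default p-value is the two-sided continuity-corrected
normal approximation `z = (|S|−1)/√var_S` with the tie-corrected null
variance `var_S = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18` (125 for n = 10
tie-free).  n = 10 is small for a normal approximation, but this is the
estimator whose p-values are the published convention for decile-median
trend tables, and the implementation reproduces the canonical n = 10 values
(S = −45 → 8.30×10⁻⁵, S = −1 → 1.00) to three significant figures.  For
rigour an **exact** method is provided: the permutation-null distribution of
S via the inversion-count recurrence (tie-free, n ≤ 12, exact integer
arithmetic) or full enumeration of the observed multiset (with ties,
n ≤ 8).  Tests verify the recurrence against exhaustive enumeration for
n ≤ 7, that exact and normal p-values agree within a factor of two for
n = 10, |S| ≤ 25, and that the exact test's rejection rate at nominal 0.05
does not exceed 0.05 under a simulated uniform-permutation null.

## Regression suite

Four models of λ on z-scored predictors (standardized in-sample over the
analysis set, so coefficients are per-s.d. effects):

1. `ols` — λ ~ ER + EO, classical OLS;
2. `ols_cbd` — adds standardized Euclidean distance from the origin centroid
   to the city-centre point (CBD);
3. `lag` — `y = ρWy + Xβ + ε`, ML;
4. `error` — `y = Xβ + u`, `u = λ_err·Wu + ε`, ML (the spatial parameter is
   named `lambda_err` throughout to avoid collision with λ_mob).

**Weights.** W is a k-nearest-neighbour graph (default k = 8) on origin
centroids, symmetrized by union, then row-standardized.  The scheme is a
package choice — k-NN is deterministic on point sets, never produces
isolated units, and with union symmetrization W = D⁻¹A with A symmetric, so
the spectrum of W equals that of the symmetric matrix D^(−1/2) A D^(−1/2)
and is real in [−1, 1].  Distance ties are broken by region-id order.  The
scheme and k are recorded in the weights metadata.

**Estimation.** Both spatial models are fitted by maximising the
concentrated log-likelihood in the single spatial parameter on
(1/min-eigenvalue, 1): for the lag model the profile is closed-form in ρ
given two residual vectors (y and Wy residualized on the design); for the
error model each evaluation is one GLS step on the spatially filtered
variables.  The Jacobian term `log det(I − ρW) = Σ log(1 − ρ·eig_k)` uses
the dense spectrum, computed once per weights object and cached; this caps
the supported size at 10⁴ units (a capability error beyond).  Both
likelihoods reduce *exactly* to the OLS likelihood at parameter 0 — asserted
algebraically in the tests.  Standard errors come from the observed
information (central-difference Hessian of the full log-likelihood over
β, spatial parameter and σ²) with normal-theory p-values.

**AIC.** `AIC = 2k − 2·loglik` with k counting intercept + slopes + σ²
(+ the spatial parameter where present): 4 for `ols`, 5 for `ols_cbd`,
`lag` and `error` at two SES predictors.  Counting σ² uniformly keeps the
four models on one scale; comparison requires an identical outcome vector
and unit set and reports Δ AIC against the best model.

The estimators follow the scikit-learn protocol (`fit`, `predict`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn tooling; `fit_ols` / `fit_spatial_lag` / `fit_spatial_error` are
thin functional wrappers.

## The synthetic city

The generator's purpose is to make every pipeline stage testable against
known ground truth, emulating the *structure* of panel-derived mobility
data, not any real geography.

* **Geometry.** Origins are a `grid_n × grid_n` tiling of `cell_km` squares;
  destinations are `dzn_block`-sized blocks of origin cells.  A configurable
  fraction of origins straddle an internal zone boundary (the shared edge of
  two adjacent origin cells is shifted half a cell), exercising the
  undefined-coverage path by construction; the tiling remains exact and
  interiors disjoint.  Real-world polygons enter only through the generic
  GeoJSON reader.
* **Populations** are uniform integers in `pop_range` (default 200–800,
  the census-block convention the origin unit mimics).
* **SES scores.** ER is standard normal; EO mixes the same draw (weight
  `rho_er_eo`, default 0.9, mimicking the strong empirical ER–EO
  correlation), the standardized distance to centre (weight `gamma_eo_dist`,
  default −0.4: high-EO areas cluster centrally) and independent noise.
  Both are mapped to the familiar area-index scale (mean 1000, s.d. 100).
  `rho² + gamma² ≤ 1` is enforced.
* **Ground truth.** `lambda_true = beta_eo·zEO + beta_er·zER +
  beta_dist·zdist + N(0, sigma_noise)` with in-sample-standardized
  covariates.  Defaults: `beta_eo = −0.1`, `beta_er = beta_dist = 0`,
  `sigma_noise = 0.2` — a moderate region-level effect against realistic
  idiosyncratic dispersion.
* **Visits.** Expected baseline daily flow i→z is
  `visit_rate · pop(i) · w_iz / Σ_z w_iz` with gravity weights
  `w = exp(−d/decay_km)` truncated at `max_radius_km = 50` (the platform's
  visit horizon); defaults `visit_rate = 0.6` visits per resident per day
  and `decay_km = 5`.  Test-period flows are baseline flows ×
  `exp(lambda_true)`.  Counts are Poisson over the window (a
  negative-binomial overdispersion hook exists via gamma mixing) and stored
  as mean counts per day; zero-count edges within the horizon are kept,
  edges beyond it are absent.
* **Coverage and panel fluctuation.** Coverage counts are Poisson with mean
  `panel_rate_base` / `panel_rate_test` per day (defaults 500 / 450 — the
  between-period panel fluctuation is not characterized by any published
  source, so it is exposed as a free parameter rather than fitted).
  Expected visit flows co-scale with the same per-period panel level, since
  visits and coverage are tallies from one device panel: the raw
  test/baseline visit ratio is therefore biased by panel fluctuation and
  the coverage normalization is what removes it.  By default coverage is
  independent of `lambda_true`, so the normalization is exercised but
  unbiased; `coverage_coupling` couples them to study normalization bias.
* **Determinism.** One global seed expands to per-stage streams via
  `SeedSequence(seed, spawn_key=(stage, substream))` with fixed stage
  numbers (0 partitions, 1 SES, 2 truth, 3 visits, 4 coverage; substream
  0/1 = baseline/test).  Identical config + seed ⇒ byte-identical outputs,
  including pipeline CSVs and manifest digests.

**What passing tests show — and do not.** Recovery of generating effects on
this city validates the *computational chain*: aggregation, exclusion,
normalization, stratification, testing, estimation.  It does not validate
the metric's behavioural assumptions on real data — constant double-counting
rates between periods, home-location fidelity, panel representativeness
across SES — none of which the generator violates by construction.

## Study conditions used in tests and the acceptance script

Simulation-based tests use a 50×50 grid (2500 origins) for recovery
ensembles (20 seeds) and smaller grids (12–40 per side) for unit and demo
tests; the acceptance script uses a 40×40 grid.  These sizes put median
standard errors well below the generated effects while keeping any single
run in seconds.  One statistical fact, established analytically and
confirmed by simulation, matters for interpreting marginal trends: with
`corr(ER, EO) = ρ` and a pure EO effect, the marginal ER-decile trend has
slope ρ times the EO trend — marginal stratification cannot null the ER
trend under strong index correlation.  A flat ER trend alongside a falling
EO trend in correlated indices requires opposing true effects
(`beta_er = −ρ·beta_eo`), the competing-effects mechanism, which the test
suite demonstrates explicitly; the bundled demo instead sets `rho_er_eo = 0`
so the marginal trends isolate the generating effects.

## Known limitations

* Planar coordinates throughout; no geodesic math (the 50 km horizon is a
  generator concern, applied to planar distances).
* Dense-spectrum spatial ML caps at 10⁴ units; no GMM/IV estimation, GWR,
  spatial Durbin or bootstrap inference.
* The grid geometry cannot produce the irregular, population-density-driven
  region shapes of real partitions; straddling origins emulate the excluded
  fringe regions by construction rather than by geometric accident.
* No temporal sub-aggregation (weekday/weekend); windows are aggregated
  whole.
* Letter-value plots and heatmaps are not rendered; the numerical tables
  are the contract.
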