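# mobishift

Socioeconomic stratification of urban mobility change from origin-destination
pass-through visit counts.

During disruptive events — lockdowns, epidemics, reopening waves — aggregate
mobility shifts unevenly across the socioeconomic landscape of a city.
`mobishift` implements, as a tested and reusable pipeline, an analysis of this
variation for cities partitioned into small origin regions (census-block
scale, with resident populations and area-level SES index scores) and coarser
destination zones in which device-panel visit counts are tallied.  It is
aimed at researchers working with panel-derived mobility aggregates who need
the full chain — metric, stratification, trend testing, spatial regression —
reproducible end to end, including on synthetic data with known ground truth.

## The statistic and the analysis chain

For each origin region the mobility change between a test period and a
pre-event baseline period is the coverage-normalised log-ratio

```
λ_mob = ln(A / B),    A = Σ_z V(i→z, T_test) / C(i, T_test),
                      B = Σ_z V(i→z, T_base) / C(i, T_base)
```

where `V(i→z, T)` is the mean daily pass-through visit count from origin `i`
into destination zone `z` during window `T`, the sum runs over zones that
neither overlap nor touch `i` (adjacent pairs are dominated by GPS jitter and
local movement, not travel), and the sample coverage `C` — the visit count in
the single zone that fully contains `i` — proxies the fluctuating size of
the device panel for that origin.  Origins not fully contained in any zone
have undefined coverage and are omitted with a reason code.

Downstream of the metric:

* **Stratification.** Two SES indices per origin — economic resources (ER)
  and education/occupation (EO) — are cut into local (in-sample, per-city)
  decile bands; the pipeline reports per-decile medians of λ_mob, joint
  10×10 ER×EO median and count grids, and letter-value summaries.
* **Trend testing.** Monotonicity of the ten decile medians is tested with
  the Mann–Kendall score S (continuity-corrected normal p-values by default;
  exact permutation-null p-values available for n ≤ 12).
* **Regression.** Four models of λ_mob on z-scored predictors: non-spatial
  OLS (ER, EO), OLS with distance to the central business district added,
  a spatial lag model `y = ρWy + Xβ + ε`, and a spatial error model
  `y = Xβ + u, u = λWu + ε`, with W a symmetrized row-standardized k-NN
  graph, fitted by maximum likelihood and compared by AIC.
* **Synthetic city.** A generator produces grid cities with correlated
  ER/EO scores, gravity-style visit flows with Poisson noise, fluctuating
  panel coverage, and a configurable true mobility-change field — so every
  stage can be validated against known ground truth.

## Worked example

```sh
mobishift validate --config configs/demo.yaml
mobishift run --config configs/demo.yaml --out runs/demo
```

The demo simulates a 40×40-cell city (1600 origins) in which mobility change
truly declines with EO (effect −0.1 per s.d.) and is unrelated to ER, then
runs the full analysis.  `runs/demo/trend_results.csv` from this run:

```
city,scenario,index,n,S,var_S,z,p_two_sided,method
synthetic,lockdown,ER,10,-3,125,-0.1788854382,0.858027657,normal_approx
synthetic,lockdown,EO,10,-45,125,-3.93547964,8.303070333e-05,normal_approx
```

The EO decile medians are perfectly monotonically decreasing (S = −45, the
extreme value for ten points, p ≈ 8.3×10⁻⁵), while the ER trend is
indistinguishable from noise (S = −3, p ≈ 0.86) — the pipeline recovers the
generating structure.  `model_summary.csv` shows all four regression models
estimating the EO coefficient near −0.1 (non-spatial OLS −0.0970, spatial
lag −0.0959) with the ER coefficient near 0 (p > 0.4), and
`model_comparison.csv` shows the spatial models offer no meaningful AIC
improvement (ΔAIC < 1 against OLS) when the generating process has no
spatial autocorrelation.

A Python-level session of the same thing:

```python
from mobishift import (CityConfig, simulate_city, find_excluded_pairs,
                       aggregate_outflow, compute_lambda)
from mobishift.strata import decile_assignment, decile_medians
from mobishift.trend import mk_test

city = simulate_city(CityConfig(grid_n=40, dzn_block=4, rho_er_eo=0.0, seed=42))
excluded = find_excluded_pairs(city.origins, city.destinations)
out_t = aggregate_outflow(city.visits, excluded, "test", origins=city.origins.ids)
out_b = aggregate_outflow(city.visits, excluded, "baseline", origins=city.origins.ids)
change = compute_lambda(out_t, out_b, city.coverage)
deciles = decile_assignment(city.seifa)
print(mk_test(decile_medians(change.lambda_mob, deciles["eo_decile"])))
# TrendResult(n=10, S=-45, var_S=125.0, z=-3.935..., p_two_sided=8.30e-05, ...)
```

## Layout

```
src/mobishift/
  synthetic.py   synthetic-city generator (partitions, SES, truth, visits, coverage)
  ingest.py      GeoJSON/CSV I/O, exclusion and coverage-container rules
  metric.py      λ_mob computation and summaries
  strata.py      decile bands, joint grids, letter values
  trend.py       Mann–Kendall score, variance, normal/exact p-values
  spatial.py     OLS + spatial lag/error estimators, weights, AIC comparison
  pipeline.py    configured end-to-end runs with manifest
  cli.py         `mobishift simulate | run | validate`
docs/methods.md  model assumptions, parameter defaults, numerical choices
```
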