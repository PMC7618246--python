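# Methods

This note documents the statistical models implemented in `heatburden`, the
synthetic worlds used to test them, the defaults and numerical choices, and
the limitations of both.

## 1. Exposure definition

A heatwave day belongs to a maximal run of at least `min_duration_days`
(default 2) consecutive days whose daily temperature is **strictly above** the
location- or cell-specific threshold: the empirical `percentile` (default
95th) of the *year-round* temperature distribution over the calibration span.
Choices worth stating explicitly:

* **Quantile convention** — linear interpolation between order statistics
  (the numpy default). Recorded in configuration so an alternative convention
  can be swapped in.
* **Ties** — a day exactly at the threshold is not an exceedance.
* **Missing temperature breaks a run**: consecutiveness cannot be certified
  across a gap, so a NaN day is never a heatwave day and splits runs.
* **Hottest months** — May–August for cells with latitude ≥ 0 (the equator is
  assigned the northern rule, the hemisphere holding more land), November–
  February for southern cells. By default the southern block stays inside the
  analysis calendar year (Jan, Feb, Nov, Dec of the same year); a
  configuration flag switches to the Nov (Y−1)–Feb (Y) reading, since either
  convention is defensible for an annual burden.
* **Regridding** — 0.25° fields are block-averaged 2×2 to 0.5°, per timestep,
  NaN-aware; misaligned grids are an error, not a silent shift.

## 2. Stage 1 — distributed-lag quasi-Poisson regression

Per location and 5-year stratum (fixed global boundaries anchored at 1973:
1973–1977, 1978–1982, …), daily deaths are regressed on:

* the distributed-lag heatwave term: x_j(t) = Σ_l HW(t−l) B[l,j], where B is
  a natural cubic spline basis over integer lags 0–10 with `df` = 4 columns
  (constant representable; internal knots equally spaced on log(lag+1), the
  standard convention concentrating flexibility at short lags — the source
  analyses do not pin down knot placement);
* a year-month factor (one dummy per calendar month within the stratum,
  ≤ 60 levels, first dropped) for seasonality and trend;
* day-of-week indicators.

The first `max_lag` days of each stratum are dropped (incomplete lag
history). Estimation is IRLS on the Poisson score equations with log link;
convergence when the relative deviance change is < 1e-9 (max 50 iterations).
The dispersion φ = Pearson χ²/(n−p) is floored at 1 — the common guard
against anti-conservative variances — and scales the covariance. The
cumulative log relative risk is θ = c′γ with c_j = Σ_l B[l,j] and variance
v = c′V_γc.

**Inclusion rules** (configurable; the source analyses state none): a
location-period enters stage 2 only with ≥ 2 full years of data, ≥ 10
heatwave days, ≥ 100 total deaths, a converged fit and finite positive v.
Rank-deficient designs raise an error naming near-collinear columns.

Sensitivity settings (max lag 14 or 21, df 6, 97.5th percentile, min/max
temperature metric) run through the identical code path.

## 3. Stage 2 — multilevel random-effects meta-regression

Model: θ_i = x_i′β + u_{loc(i)} + ε_i, u ~ N(0, τ²) shared across a
location's periods, ε_i ~ N(0, v_i) with v_i known from stage 1. A single
location-level random intercept is the simplest multilevel structure
consistent with repeated 5-year estimates per location; period-level random
effects are deliberately not added. τ² is estimated by profiled REML
(bounded 1-D minimisation with an explicit comparison against τ² = 0, since
a bounded optimiser cannot sit exactly on the boundary); β by GLS at τ̂²,
using Sherman–Morrison per location block so no dense n×n solve occurs.
BLUPs are posterior means û = τ²·1′V_b⁻¹(θ_b − X_bβ̂); for a single-estimate
location this is the familiar shrinkage τ²/(τ²+v)·residual.

Design: intercept; climate-zone and region dummies (first level dropped);
log GDP per capita (GDP spans orders of magnitude — configurable); annual
mean temperature; annual temperature range; period midpoint centred at the
sample mean and extrapolated linearly to the analysis year; climate-zone ×
mean-temperature and mean-temperature × temperature-range interactions.
Unseen categorical levels at prediction time raise an error listing the
level — never a silent fallback. Grid prediction uses fixed effects only
(no BLUP exists for unobserved cells), with variance x′V_βx. Wald inference
throughout; no small-sample (Knapp–Hartung) adjustment.

Pooling acts on the scalar cumulative log-RR, not the vector of lag-basis
coefficients; a multivariate extension would change the reduction step only.

## 4. Stage 3 — baseline mortality and burden

* Country annual mortality rates 2000–2019 are interpolated to 2023 by a
  natural cubic spline; beyond the data range the natural tail is **linear**
  (extrapolating rather than refusing, because the analysis year lies outside
  the observed rates by construction), floored at 0. Under 4 observed years
  the fallback is a linear trend with a warning.
* Annual deaths = rate × population; only cells with ≥ 1 annual death enter
  the analysis (the population share excluded this way is checked against
  the generator's truth in tests).
* The hottest-month death ratio is OLS of observed location-year ratios on
  annual mean temperature, annual temperature range, region, climate zone and
  log GDP. Plain OLS on the raw ratio is a choice — the source analyses do
  not state link or weighting — and predictions are clipped to [0.05, 0.95]
  because OLS can leave (0,1).
* D_g = annual deaths × predicted ratio / days in the cell's hottest months
  (leap-year aware; 123 northern / 120 southern days in 2023).
* ED_g = (RR_g − 1)·N_g·D_g; negative cell contributions (RR_g < 1) are kept
  in all sums — truncation would bias aggregates and the published intervals
  themselves include negative bounds.
* Aggregates per region and globally: ED, ratio (% of hottest-month deaths),
  rate (per million), regional proportion (% of global ED).

**Uncertainty.** 500 Monte Carlo draws of β from N(β̂, V_β) (nearest-PSD
repair by eigenvalue clipping if needed), with N_g and D_g held fixed; eCIs
are 2.5th–97.5th percentile bands recomputed per aggregate. Only stage-2
coefficient uncertainty is propagated: stage-1 sampling noise enters through
V_β via the GLS weights, but D_g uncertainty and climate-model spread outside
the attribution step do not — a documented limitation, matching the minimal
reading of coefficient-simulation eCIs.

## 5. Attribution

Bias correction is an additive per-cell, per-calendar-month climatology
delta: corrected = series + (reference clim − model-factual clim) over the
calibration span, with the *same* offsets applied to factual and
counterfactual series — preserving their difference exactly. Full quantile
mapping is left as a configuration extension point; the additive scheme is
deterministic and testable. Thresholds for scenario detection come from the
corrected factual climate (the counterfactual asks "same thresholds,
different weather"). The contribution rate (ED_f − ED_cf)/ED_f is computed
per aggregation unit, pooled across climate models by unweighted mean (four
models, no stated weights), and multiplied onto the stage-3 ED. Attribution
eCIs extend the burden Monte Carlo by resampling one model index uniformly
per coefficient draw. ED_f = 0 yields a missing proportion, not a zero.

## 6. The synthetic world

The generator emulates the statistical structure the analysis assumes, with
recorded ground truth:

* **Temperature**: seasonal sinusoid (amplitude from the location's annual
  range, peak mid-July north / mid-January south) + AR(1) noise (σ = 2 °C,
  ρ = 0.7) + Markov-persistent hot spells confined to the hottest months
  (start ~3%/day, persistence 0.65, boosts of 3–6 °C), so multi-day
  exceedance runs occur at a controllable rate.
* **Mortality**: negative binomial in the mean/dispersion parameterisation
  (variance = φ·mean, default φ = 1.3) — the generative counterpart of the
  quasi-Poisson mean-variance assumption, which itself has no generative
  form. The log-mean holds calendar-month step effects (winter-peaked, with
  amplitude increasing in the annual temperature range so a real
  seasonality gradient exists for the death-ratio model to recover),
  day-of-week effects, and the true lag-distributed heatwave effect. Using
  month-step seasonality makes the stage-1 year-month factor exactly
  correctly specified, so recovery tests measure the estimator rather than
  seasonal confounding. Deaths respond to the *detected* heatwave indicator,
  making the recorded true cumulative log-RR exactly the stage-1 estimand.
* **Truth centring**: per-location true log-RRs are the population value
  plus meta-predictor shifts centred at the realised sample means, so the
  across-location mean equals the configured value exactly.
* **Grid**: 0.5°-spaced cells spanning both hemispheres, smooth latitudinal
  meta-predictor gradients, deterministic country blocks with *exactly
  linear* 2000–2019 mortality-rate trends (so the spline's linear tail
  extrapolates them without error and the true 2023 rate is closed-form),
  log-normal population, per-cell true death ratios from the same
  month-effect curve.
* **Scenarios**: all models share the reference weather; factual_m =
  reference + month-dependent model bias, counterfactual_m = factual_m −
  warming offset (default 1 °C), so the factual−counterfactual difference is
  exactly the offset and additive monthly correction removes the bias
  exactly.
* **Constructed attribution testbed**: the counterfactual cools whole
  factual heatwave runs (greedily chosen to remove as close as possible to
  half of each cell's hottest-month heatwave days) well below threshold, so
  the true attributable fraction is known exactly per cell, ≈ 0.5 overall.
* **Reduced worlds** for stage-2 and interval-coverage experiments sample
  effect estimates directly from the stage-2 model in the fitted design's
  own coordinates (known β, τ, v_i), isolating those stages from stage-1
  noise; the full stage-1 route is exercised separately at full size.

What the generator does **not** emulate: spatial covariance of temperature
between cells, pandemic-era mortality shocks, age structure, population
trends, humidity. Passing recovery tests therefore demonstrates correctness
of the estimation machinery under the model's own assumptions — not
robustness to the ways real mortality and climate data violate them.

## 7. Reference experiment sizes

The evaluation experiments (shared by the acceptance tests and
`scripts/acceptance.py`) use: 100 locations × 10 years for stage-1 recovery
(true cumulative RR 1.15, ~300 location-periods); 140 locations (~420
location-periods) for the null size; 100 replicate reduced worlds of 50
locations × 2 periods for stage-2 coefficient coverage (a main-effects
design, where per-coefficient 2-SE coverage is the meaningful target — joint
coverage across all coefficients would be ~0.95^p by construction); 200
reduced worlds of 20 locations with 200 draws for eCI coverage; 20
constructed worlds for attribution recovery. These sizes give Monte-Carlo
error comfortably inside each check's tolerance.

## 8. Known limitations

* Quasi-Poisson point estimates coincide with Poisson ML, so the negative
  binomial generator slightly over-states v_i heterogeneity relative to a
  quasi-likelihood world; the dispersion floor at 1 is conservative.
* eCIs omit D_g and per-model climate uncertainty outside the attribution
  model-resampling step.
* The death-ratio OLS can be mis-calibrated outside the range of observed
  meta-predictors; clipping bounds the damage but is itself ad hoc.
* Local-time daily aggregation from hourly fields is out of scope: synthetic
  grids are generated daily. The regridding operator is retained for
  externally supplied 0.25° fields.
* Stage caching is coarse (per-stage outputs on disk, rerunnable via the
  CLI subcommands); there is no content-addressed incremental cache.
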