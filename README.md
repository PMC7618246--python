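# heatburden

Estimating heatwave-related excess mortality on a 0.5° grid, and the share of
that burden attributable to human-induced climate change.

`heatburden` is a research-grade re-implementation of the three-stage
modelling framework used in global heatwave health-impact assessments, aimed
at environmental epidemiologists and climate-health modellers who want a
tested, reproducible pipeline they can run end to end on synthetic data — or
point at their own location series and gridded temperature fields.

## The model

**Exposure.** A *heatwave day* is a day belonging to a run of ≥ 2 consecutive
days whose daily mean temperature lies strictly above the location-specific
95th percentile of the year-round calibration distribution. The percentile,
run length and temperature metric (mean/min/max) are configurable.

**Stage 1 — location × period regression.** For each location and consecutive
5-year stratum, daily death counts are modelled by quasi-Poisson time-series
regression (log link, Poisson score equations solved by IRLS, Pearson
dispersion):

    log E[Y_t] = α + f(HW, lag 0…10) + year-month factor + day-of-week

where the heatwave term is a distributed lag with a natural cubic spline
basis (4 df) over lags 0–10. The lag coefficients reduce to a cumulative log
relative risk θ = c′γ with variance v = c′Vc — the multiplicative change in
mortality per heatwave day integrated over its delayed effects.

**Stage 2 — meta-regression.** The (θ, v) pairs are pooled in a multilevel
random-effects meta-regression θ_i = x_i′β + u_loc + ε_i with a location-level
random intercept (τ² by REML, β by GLS, per-location BLUPs). The design x_i
holds five meta-predictors — climate zone, region, log GDP per capita, annual
mean temperature, annual temperature range — the centred period midpoint as a
linear time effect, and climate-zone × mean-temperature and
mean-temperature × temperature-range interactions.

**Stage 3 — gridded burden.** Fixed-effect predictions give each grid cell's
RR_g for the analysis year. With N_g the cell's heatwave days during its
hemisphere-specific hottest months (May–Aug north / Nov–Feb south) and D_g
its daily baseline deaths (country mortality rates 2000–2019 interpolated to
2023 by natural spline, converted via gridded population, and scaled by a
regression-predicted hottest-month death ratio):

    ED_g = (RR_g − 1) × N_g × D_g

Excess deaths, the excess death ratio (% of hottest-month deaths) and rate
(per million people) are aggregated by region and globally, with 95%
empirical confidence intervals from 500 Monte Carlo draws of β.

**Attribution.** Factual and counterfactual climate-model grids are
bias-corrected against the reference series by additive monthly-climatology
deltas (the same offsets for both scenarios), heatwave days are recomputed per
scenario with thresholds from the corrected factual climate, and the
contribution rate (ED_f − ED_cf)/ED_f — pooled over models by unweighted
mean — is multiplied onto the stage-3 burden.

A synthetic-world generator emulates every input with known ground truth
(true cumulative log-RR per location, true death ratios, warming offset,
model bias), so each stage is tested as a parameter-recovery problem.

## Worked example

```python
from heatburden.config import WorldConfig, PipelineConfig
from heatburden.pipeline import run_pipeline

cfg = PipelineConfig(
    world=WorldConfig(n_locations=40, start_year=2010, end_year=2019, seed=11,
                      grid_shape=(6, 8), country_block=(3, 4)),
    n_sim=500, seed=11,
)
res = run_pipeline(cfg)
print(res.burden[["excess_deaths", "excess_deaths_lo", "excess_deaths_hi",
                  "excess_death_ratio_pct", "excess_death_rate_per_million",
                  "proportion_pct"]].round(2))
```

prints

```
        excess_deaths  excess_deaths_lo  excess_deaths_hi  excess_death_ratio_pct  excess_death_rate_per_million  proportion_pct
region
global         145.62             93.28            199.23                    2.14                          48.87           49.38
R1              45.34             28.22             63.56                    2.87                          77.70           45.70
R2              36.68             20.59             55.35                    1.96                          53.74           52.36
R3              31.76             18.15             46.83                    2.96                          58.68           41.33
R4              31.84             18.33             45.91                    1.40                          27.16           59.19
```

Reading the global row: the synthetic 2023 heatwave season causes ~146 excess
deaths across the 48-cell world (95% eCI 93–199), 2.1% of all hottest-month
deaths, or ~49 per million people; about 49% of that burden disappears in the
counterfactual without the configured 1 °C warming offset. On the estimation
side the world's true mean cumulative log-RR is 0.1398 (RR 1.15) and the 120
stage-1 estimates average 0.1367 — recovery within Monte-Carlo error.

The same run is available from the shell:

```bash
heatburden run-all --out runs/demo --seed 11
```

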