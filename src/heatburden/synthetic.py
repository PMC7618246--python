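"""Synthetic world generator.

Everything the real analysis would read from external archives — per-location
daily mortality/temperature series with meta-predictors, gridded daily
temperature, population, country mortality rates, and factual/counterfactual
climate-model scenario pairs — is generated here with *known ground truth* so
that every downstream stage can be tested as a parameter-recovery problem.

Ground-truth bookkeeping:

* each location's true cumulative log relative risk of a heatwave day
  (population value plus meta-predictor shifts, centred so the across-location
  mean equals ``true_cum_log_rr``);
* each location's and grid cell's true hottest-month death ratio (implied by
  the winter-peaked month-effect curve used to modulate baseline mortality);
* the warming offset between factual and counterfactual scenario temperatures
  and each model's additive bias against the reference series;
* for the constructed attribution testbed, the exact per-cell fraction of
  factual heatwave days removed from the counterfactual.

Mortality counts are negative binomial in the mean/dispersion
parameterisation (variance = dispersion x mean), the generative counterpart of
the quasi-Poisson mean-variance assumption used in estimation.  Deaths respond
to the *detected* heatwave indicator (threshold plus run rule applied to the
generated temperatures), so the recorded true log-RR is exactly the estimand
of the first-stage regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .config import ConfigError, WorldConfig
from .heatwave import detect_heatwaves, hottest_months, percentile_threshold

__all__ = [
    "MetaPredictors",
    "LocationSeries",
    "GridWorld",
    "ScenarioPair",
    "generate_locations",
    "generate_grid_world",
    "generate_scenarios",
    "constructed_scenario_pair",
    "generate_reduced_world",
    "true_hot_month_ratio",
]

CLIMATE_ZONES = ("A", "B", "C", "D", "E")
REGIONS = ("R1", "R2", "R3", "R4")
DOW_EFFECTS = np.array([0.00, 0.01, 0.02, 0.00, -0.01, -0.03, 0.01])


@dataclass(frozen=True)
class MetaPredictors:
    """The five location-level meta-predictors used in stage 2."""

    climate_zone: str
    region: str
    gdp_per_capita: float
    annual_mean_temp: float
    annual_temp_range: float

    def __post_init__(self) -> None:
        if self.climate_zone not in CLIMATE_ZONES:
            raise ValueError(f"unknown climate zone {self.climate_zone!r}")
        if self.annual_temp_range <= 0:
            raise ValueError("annual_temp_range must be positive")
        if self.gdp_per_capita <= 0:
            raise ValueError("gdp_per_capita must be positive")


@dataclass
class LocationSeries:
    """One location's daily series plus its meta-predictors and truth."""

    location_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    deaths: np.ndarray
    meta: MetaPredictors
    latitude: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.tmean) or len(self.dates) != len(self.deaths):
            raise ValueError("dates/tmean/deaths length mismatch")
        if np.any(self.deaths < 0):
            raise ValueError("deaths must be non-negative")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "tmean": self.tmean, "deaths": self.deaths}
        )


@dataclass
class GridWorld:
    """Gridded bundle: daily temperature, population, countries, rates, meta."""

    tmean: xr.DataArray  # (time, lat, lon)
    population: xr.DataArray  # (lat, lon)
    country_id: np.ndarray  # (lat, lon) of str
    country_rates: pd.DataFrame  # columns: country_id, year, rate
    cells: pd.DataFrame  # one row per cell: meta-predictors + truth columns
    feature_centers: dict

    @property
    def lat(self) -> np.ndarray:
        return self.tmean["lat"].values

    @property
    def lon(self) -> np.ndarray:
        return self.tmean["lon"].values


@dataclass
class ScenarioPair:
    """Factual/counterfactual daily grids from one climate model, with the
    reference (reanalysis-role) series used for bias correction."""

    model_id: str
    factual: xr.DataArray
    counterfactual: xr.DataArray
    reference: xr.DataArray
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.factual.shape != self.counterfactual.shape:
            raise ValueError("factual/counterfactual geometry mismatch")


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------


def _season_peak_doy(latitude: float) -> float:
    return 196.0 if latitude >= 0 else 15.0


def _death_peak_month(latitude: float) -> int:
    # mortality peaks in the local winter
    return 1 if latitude >= 0 else 7


def _month_effect(months: np.ndarray, amplitude: float, peak_month: int) -> np.ndarray:
    return amplitude * np.cos(2.0 * np.pi * (months - peak_month) / 12.0)


def true_hot_month_ratio(latitude: float, amplitude: float, year: int = 2023) -> float:
    """Fraction of annual deaths falling in the hottest months implied by the
    winter-peaked month-effect mortality curve."""
    months = np.arange(1, 13)
    days = np.array(
        [pd.Timestamp(year=year, month=m, day=1).days_in_month for m in months]
    )
    w = days * np.exp(_month_effect(months, amplitude, _death_peak_month(latitude)))
    hot = np.isin(months, list(hottest_months(latitude)))
    return float(w[hot].sum() / w.sum())


def _ar1(n: int, sigma: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(0.0, sigma * np.sqrt(1 - rho**2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sigma)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + eps[t]
    return out


def _episode_boost(
    dates: pd.DatetimeIndex,
    latitude: float,
    rng: np.random.Generator,
    p_start: float = 0.03,
    p_persist: float = 0.65,
    boost_range: tuple[float, float] = (3.0, 6.0),
) -> np.ndarray:
    """Markov-persistent hot-spell boosts, confined to the hottest months so
    multi-day exceedance runs occur at a controllable rate."""
    hot = np.isin(dates.month, list(hottest_months(latitude)))
    n = len(dates)
    boost = np.zeros(n)
    state = False
    current = 0.0
    for t in range(n):
        if not hot[t]:
            state = False
            continue
        if state:
            state = rng.random() < p_persist
        else:
            state = rng.random() < p_start
            if state:
                current = rng.uniform(*boost_range)
        if state:
            boost[t] = current
    return boost


def _temperature_series(
    dates: pd.DatetimeIndex,
    latitude: float,
    mean_temp: float,
    temp_range: float,
    rng: np.random.Generator,
    episode_kwargs: dict | None = None,
) -> np.ndarray:
    doy = dates.dayofyear.values.astype(float)
    seasonal = mean_temp + 0.5 * temp_range * np.cos(
        2.0 * np.pi * (doy - _season_peak_doy(latitude)) / 365.25
    )
    noise = _ar1(len(dates), sigma=2.0, rho=0.7, rng=rng)
    boost = _episode_boost(dates, latitude, rng, **(episode_kwargs or {}))
    return seasonal + noise + boost


def _nb_draw(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Counts with mean mu and variance dispersion * mu."""
    if dispersion <= 1.0 + 1e-12:
        return rng.poisson(mu)
    r = mu / (dispersion - 1.0)
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _sample_meta(
    n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample latitudes and the five meta-predictors for ``n`` locations."""
    south = rng.random(n) < 0.30
    lat = np.where(
        south, rng.uniform(-45.0, -5.0, n), rng.uniform(5.0, 65.0, n)
    )
    mean_temp = 28.0 - 0.4 * np.abs(lat) + rng.normal(0.0, 2.0, n)
    temp_range = np.clip(6.0 + 0.35 * np.abs(lat) + rng.normal(0.0, 1.5, n), 2.0, None)
    gdp = np.exp(rng.normal(9.5, 0.7, n))
    zone = np.select(
        [mean_temp >= 24, mean_temp >= 18, mean_temp >= 12, mean_temp >= 6],
        ["A", "B", "C", "D"],
        default="E",
    )
    region = rng.choice(REGIONS, size=n)
    df = pd.DataFrame(
        {
            "latitude": lat,
            "climate_zone": zone,
            "region": region,
            "gdp_per_capita": gdp,
            "annual_mean_temp": mean_temp,
            "annual_temp_range": temp_range,
        }
    )
    return df, lat


def _true_thetas(
    meta_df: pd.DataFrame, config: WorldConfig
) -> tuple[np.ndarray, dict]:
    """Per-location true cumulative log-RR, centred so the sample mean equals
    ``true_cum_log_rr`` exactly."""
    coefs = config.meta_effect_coefs or {}
    t = meta_df["annual_mean_temp"].to_numpy()
    r = meta_df["annual_temp_range"].to_numpy()
    g = np.log(meta_df["gdp_per_capita"].to_numpy())
    centers = {
        "annual_mean_temp": float(t.mean()),
        "annual_temp_range": float(r.mean()),
        "log_gdp": float(g.mean()),
    }
    tc, rc, gc = t - centers["annual_mean_temp"], r - centers["annual_temp_range"], g - centers["log_gdp"]
    shift = (
        coefs.get("annual_mean_temp", 0.0) * tc
        + coefs.get("annual_temp_range", 0.0) * rc
        + coefs.get("log_gdp", 0.0) * gc
    )
    inter = tc * rc
    shift = shift + coefs.get("mean_temp_x_range", 0.0) * (inter - inter.mean())
    return config.true_cum_log_rr + shift, centers


# ---------------------------------------------------------------------------
# location series
# ---------------------------------------------------------------------------


def generate_locations(
    config: WorldConfig, rng: np.random.Generator | None = None
) -> list[LocationSeries]:
    """Generate per-location daily temperature/mortality series.

    Temperature is a seasonal sinusoid plus AR(1) noise plus injected
    multi-day hot spells.  Deaths are negative binomial with a log-mean built
    from calendar-month effects, day-of-week effects, and the true
    lag-distributed effect of the detected heatwave indicator.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    meta_df, lat = _sample_meta(config.n_locations, rng)
    thetas, centers = _true_thetas(meta_df, config)
    dates = pd.date_range(
        f"{config.start_year}-01-01", f"{config.end_year}-12-31", freq="D"
    )
    lag_w = np.asarray(config.lag_weights)
    out: list[LocationSeries] = []
    for i in range(config.n_locations):
        row = meta_df.iloc[i]
        tmean = _temperature_series(
            dates, lat[i], row.annual_mean_temp, row.annual_temp_range, rng
        )
        series = pd.Series(tmean, index=dates)
        thr = percentile_threshold(series, config.heatwave)
        cal = detect_heatwaves(series, thr, config.heatwave)
        hw = cal.indicator.astype(float)
        # lag-distributed exposure: sum_l w_l * HW(t - l); pre-sample history is 0
        lagged = np.convolve(hw, lag_w)[: len(hw)]
        amp = 0.08 + 0.004 * row.annual_temp_range
        log_mu = (
            np.log(config.baseline_deaths_per_day)
            + _month_effect(dates.month.values, amp, _death_peak_month(lat[i]))
            + DOW_EFFECTS[dates.dayofweek.values]
            + thetas[i] * lagged
        )
        deaths = _nb_draw(np.exp(log_mu), config.dispersion, rng)
        meta = MetaPredictors(
            climate_zone=row.climate_zone,
            region=row.region,
            gdp_per_capita=float(row.gdp_per_capita),
            annual_mean_temp=float(row.annual_mean_temp),
            annual_temp_range=float(row.annual_temp_range),
        )
        out.append(
            LocationSeries(
                location_id=f"loc{i:04d}",
                dates=dates,
                tmean=tmean,
                deaths=deaths.astype(np.int64),
                meta=meta,
                latitude=float(lat[i]),
                truth={
                    "true_cum_log_rr": float(thetas[i]),
                    "true_death_ratio": true_hot_month_ratio(lat[i], amp),
                    "threshold": thr,
                    "n_heatwave_days": int(hw.sum()),
                    "feature_centers": centers,
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# gridded world
# ---------------------------------------------------------------------------


def generate_grid_world(
    config: WorldConfig,
    rng: np.random.Generator | None = None,
    episode_kwargs: dict | None = None,
    allowed_zones: list[str] | None = None,
    allowed_regions: list[str] | None = None,
) -> GridWorld:
    """Generate the gridded bundle: daily temperature over the calibration
    span through the analysis year, population, synthetic countries with
    linearly trending 2000-2019 mortality rates, and per-cell meta-predictors
    with recorded truth (true log-RR shift, true hottest-month death ratio,
    true 2023 rate)."""
    if config.grid_shape[0] * config.grid_shape[1] <= 0:
        raise ConfigError("grid has zero cells")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    nlat, nlon = config.grid_shape
    lats = config.grid_lat_start + 0.5 * np.arange(nlat)
    lons = config.grid_lon_start + 0.5 * np.arange(nlon)
    start = config.calibration_years[0]
    dates = pd.date_range(f"{start}-01-01", f"{config.analysis_year}-12-31", freq="D")

    # cell-level meta fields: smooth latitudinal gradient + noise
    lat2d = np.repeat(lats[:, None], nlon, axis=1)
    mean_c = 28.0 - 0.4 * np.abs(lat2d) + rng.normal(0.0, 2.0, size=lat2d.shape)
    range_c = np.clip(
        6.0 + 0.35 * np.abs(lat2d) + rng.normal(0.0, 1.5, size=lat2d.shape), 2.0, None
    )
    zone_c = np.select(
        [mean_c >= 24, mean_c >= 18, mean_c >= 12, mean_c >= 6],
        ["A", "B", "C", "D"],
        default="E",
    )
    if allowed_zones is not None:
        # clamp to the nearest zone (by warmth ordering) present in the
        # estimation sample, so grid prediction never sees an unknown level
        order = {z: k for k, z in enumerate(CLIMATE_ZONES)}
        allowed_idx = np.array(sorted(order[z] for z in allowed_zones))
        idx = np.vectorize(order.get)(zone_c)
        nearest = allowed_idx[
            np.argmin(np.abs(idx.ravel()[:, None] - allowed_idx[None, :]), axis=1)
        ].reshape(idx.shape)
        zone_c = np.vectorize(lambda k: CLIMATE_ZONES[k])(nearest)
    # regions: longitude quadrants
    region_c = np.empty(lat2d.shape, dtype=object)
    region_pool = list(allowed_regions) if allowed_regions is not None else list(REGIONS)
    qs = np.array_split(np.arange(nlon), min(4, len(region_pool)))
    for q, cols in enumerate(qs):
        region_c[:, cols] = region_pool[q % len(region_pool)]

    # countries: deterministic blocks of cells
    bi, bj = config.country_block
    country = np.empty(lat2d.shape, dtype=object)
    for i in range(nlat):
        for j in range(nlon):
            country[i, j] = f"C{(i // bi) * ((nlon + bj - 1) // bj) + j // bj:03d}"
    countries = sorted(set(country.ravel()))

    gdp_country = {c: float(np.exp(rng.normal(9.5, 0.7))) for c in countries}
    gdp_c = np.vectorize(gdp_country.get)(country)

    # country mortality rates 2000-2019: exactly linear trends, so the natural
    # spline's linear tail extrapolates them without error and the true 2023
    # rate is known in closed form
    years = np.arange(2000, 2020)
    recs = []
    true_rate_2023 = {}
    for c in countries:
        base = rng.uniform(0.007, 0.012)
        slope = rng.uniform(-0.00008, -0.00002)
        rates = base + slope * (years - 2000)
        true_rate_2023[c] = float(base + slope * (2023 - 2000))
        recs.extend({"country_id": c, "year": int(y), "rate": float(r)} for y, r in zip(years, rates))
    country_rates = pd.DataFrame(recs)

    population = np.exp(rng.normal(10.5, 1.0, size=lat2d.shape))

    # daily temperature per cell
    temps = np.empty((len(dates), nlat, nlon), dtype=np.float32)
    for i in range(nlat):
        for j in range(nlon):
            temps[:, i, j] = _temperature_series(
                dates, float(lats[i]), mean_c[i, j], range_c[i, j], rng,
                episode_kwargs=episode_kwargs,
            )
    tmean = xr.DataArray(
        temps,
        coords={"time": dates, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name="tmean",
    )

    # per-cell truth
    cfg_centers_df = pd.DataFrame(
        {
            "annual_mean_temp": mean_c.ravel(),
            "annual_temp_range": range_c.ravel(),
            "gdp_per_capita": gdp_c.ravel().astype(float),
        }
    )
    theta_shift, centers = _true_thetas(cfg_centers_df, config)
    amps = 0.08 + 0.004 * range_c
    true_ratio = np.array(
        [
            true_hot_month_ratio(float(lats[i]), amps[i, j], config.analysis_year)
            for i in range(nlat)
            for j in range(nlon)
        ]
    )
    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    cells = pd.DataFrame(
        {
            "cell_id": [f"g{i:03d}_{j:03d}" for i, j in zip(ii.ravel(), jj.ravel())],
            "ilat": ii.ravel(),
            "ilon": jj.ravel(),
            "lat": lat2d.ravel(),
            "lon": np.tile(lons, nlat),
            "country_id": country.ravel(),
            "region": region_c.ravel(),
            "climate_zone": zone_c.ravel(),
            "gdp_per_capita": gdp_c.ravel().astype(float),
            "annual_mean_temp": mean_c.ravel(),
            "annual_temp_range": range_c.ravel(),
            "population": population.ravel(),
            "true_cum_log_rr": theta_shift,
            "true_death_ratio": true_ratio,
            "true_rate_2023": [true_rate_2023[c] for c in country.ravel()],
        }
    )
    pop_da = xr.DataArray(
        population, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"), name="population"
    )
    return GridWorld(
        tmean=tmean,
        population=pop_da,
        country_id=country,
        country_rates=country_rates,
        cells=cells,
        feature_centers=centers,
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

_MODEL_BIAS_SCALE = (1.0, 0.5, -0.5, -1.0)


def generate_scenarios(
    config: WorldConfig, world: GridWorld
) -> list[ScenarioPair]:
    """Factual/counterfactual pairs for ``config.n_models`` climate models.

    All pairs share the reference weather (the grid world's daily temperature);
    factual_m = reference + bias_m(month), counterfactual_m = factual_m -
    warming_offset_C, so the factual-counterfactual difference is exactly the
    warming offset and the bias is removable by monthly-climatology deltas.
    """
    ref = world.tmean
    months = ref["time"].dt.month
    pairs = []
    for m in range(config.n_models):
        scale = _MODEL_BIAS_SCALE[m % len(_MODEL_BIAS_SCALE)]
        # month-dependent additive bias, distinct per model
        bias = config.model_bias_C * scale * (
            1.0 + 0.3 * np.sin(2.0 * np.pi * months / 12.0)
        )
        factual = ref + bias
        counterfactual = factual - config.warming_offset_C
        pairs.append(
            ScenarioPair(
                model_id=f"model_{m}",
                factual=factual.rename("tmean"),
                counterfactual=counterfactual.rename("tmean"),
                reference=ref,
                truth={
                    "warming_offset_C": config.warming_offset_C,
                    "bias_scale": scale,
                },
            )
        )
    return pairs


def constructed_scenario_pair(
    config: WorldConfig,
    world: GridWorld,
    model_id: str = "constructed",
    target_fraction: float = 0.5,
) -> ScenarioPair:
    """Counterfactual with a *known* attributable fraction of heatwave days.

    Factual = reference weather.  Per cell, maximal heatwave runs of the
    analysis year (detected with the configured definition and
    calibration-span thresholds) are cooled well below the threshold, chosen
    greedily so the removed share of *hottest-month* heatwave days is as close
    as possible to ``target_fraction``.  The realised per-cell and overall
    removed fractions — the true attributable fractions — are recorded in
    ``truth``.
    """
    from .heatwave import _run_indicator, grid_thresholds, hottest_months  # noqa: PLC0415

    defn = config.heatwave
    ref = world.tmean
    defn_cal = defn
    if defn.calibration_start is None:
        defn_cal = HeatwaveDefinitionWithSpan(defn, *config.calibration_years)
    thr = grid_thresholds(ref, defn_cal)
    time = pd.DatetimeIndex(ref["time"].values)
    in_year = (time.year == config.analysis_year).to_numpy() if hasattr(
        time.year == config.analysis_year, "to_numpy"
    ) else np.asarray(time.year == config.analysis_year)
    month = time.month.values if hasattr(time.month, "values") else np.asarray(time.month)
    lats = ref["lat"].values
    arr = ref.transpose("time", "lat", "lon").values.copy()
    thrv = thr.transpose("lat", "lon").values
    removed = np.zeros(thrv.shape, dtype=np.int64)
    kept = np.zeros(thrv.shape, dtype=np.int64)
    for i in range(arr.shape[1]):
        hot_mask = in_year & np.isin(month, list(hottest_months(float(lats[i]))))
        for j in range(arr.shape[2]):
            above = arr[:, i, j] > thrv[i, j]
            ind = _run_indicator(above, defn.min_duration_days).astype(bool)
            run_year = ind & in_year
            d = np.diff(run_year.astype(np.int8))
            starts = list(np.flatnonzero(d == 1) + 1)
            ends = list(np.flatnonzero(d == -1) + 1)
            if run_year[0]:
                starts.insert(0, 0)
            if run_year[-1]:
                ends.append(len(run_year))
            runs = [(s, e, int(hot_mask[s:e].sum())) for s, e in zip(starts, ends)]
            total_w = sum(w for _, _, w in runs)
            if total_w == 0:
                continue
            target = target_fraction * total_w
            got = 0
            for s, e, w in sorted(runs, key=lambda r: -r[2]):
                if abs(got + w - target) < abs(got - target):
                    arr[s:e, i, j] = thrv[i, j] - 5.0
                    got += w
            removed[i, j] = got
            kept[i, j] = total_w - got
    cf = xr.DataArray(arr, coords=ref.coords, dims=ref.dims, name="tmean")
    total = removed + kept
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, removed / np.maximum(total, 1), np.nan)
    return ScenarioPair(
        model_id=model_id,
        factual=ref.copy(),
        counterfactual=cf,
        reference=ref,
        truth={
            "removed_days": removed,
            "kept_days": kept,
            "true_fraction_by_cell": frac,
            "true_fraction_overall": float(removed.sum() / max(total.sum(), 1)),
        },
    )


def HeatwaveDefinitionWithSpan(defn, start, end):
    """Copy a definition with an explicit calibration span."""
    from dataclasses import replace

    return replace(defn, calibration_start=start, calibration_end=end)


# ---------------------------------------------------------------------------
# reduced worlds (stage-2 / uncertainty testbeds)
# ---------------------------------------------------------------------------


def generate_reduced_world(
    n_locations: int,
    rng: np.random.Generator,
    n_periods: int = 2,
    beta_true: dict[str, float] | None = None,
    tau: float = 0.02,
    se_range: tuple[float, float] = (0.03, 0.08),
    n_cells: int = 0,
    design_kwargs: dict | None = None,
):
    """Sample first-stage effect estimates directly from the stage-2 model.

    Rather than simulating daily series and refitting the distributed-lag
    regressions, this draws per-location-period estimates
    theta_hat_i = x_i' beta + u_loc + eps_i with u ~ N(0, tau^2) and
    eps_i ~ N(0, v_i) at known v_i, in exactly the coordinates of the fitted
    meta-design — so stage-2 recovery and interval coverage can be tested in
    isolation with closed-form truth.

    Returns a dict with the effects table, the fitted design builder, the true
    coefficient vector, and (optionally) grid-like cells with true log-RR.
    """
    from .stage2 import MetaDesign  # noqa: PLC0415

    meta_df, _ = _sample_meta(n_locations, rng)
    meta_df["location_id"] = [f"loc{i:04d}" for i in range(n_locations)]
    midpoints = 2010.0 + 5.0 * np.arange(n_periods)
    rows = meta_df.loc[meta_df.index.repeat(n_periods)].reset_index(drop=True)
    rows["midpoint"] = np.tile(midpoints, n_locations)

    builder = MetaDesign(**(design_kwargs or {"use_interactions": False,
                                              "use_zones": False, "use_regions": False}))
    X = builder.fit_transform(rows, rows["midpoint"].to_numpy())
    cols = list(X.columns)
    if beta_true is None:
        beta_true = {c: 0.0 for c in cols}
        beta_true["intercept"] = float(np.log(1.15))
        for c, v in {
            "annual_mean_temp": 0.004,
            "annual_temp_range": -0.003,
            "log_gdp": -0.02,
            "midpoint": 0.001,
        }.items():
            if c in beta_true:
                beta_true[c] = v
    beta_vec = np.array([beta_true.get(c, 0.0) for c in cols])
    theta_true = X.to_numpy() @ beta_vec
    u = rng.normal(0.0, tau, size=n_locations)
    se = rng.uniform(*se_range, size=len(rows))
    theta_hat = theta_true + np.repeat(u, n_periods) + rng.normal(0.0, se)
    effects = pd.DataFrame(
        {
            "location_id": rows["location_id"],
            "midpoint": rows["midpoint"],
            "theta": theta_hat,
            "variance": se**2,
            "converged": True,
        }
    )
    out = {
        "effects": effects,
        "meta": rows,
        "design": builder,
        "X": X,
        "beta_true": beta_vec,
        "beta_names": cols,
        "tau": tau,
    }
    if n_cells > 0:
        idx = rng.integers(0, n_locations, size=n_cells)
        cells = meta_df.iloc[idx].reset_index(drop=True).copy()
        cells["annual_mean_temp"] += rng.normal(0.0, 0.5, n_cells)
        cells["annual_temp_range"] = np.clip(
            cells["annual_temp_range"] + rng.normal(0.0, 0.3, n_cells), 2.0, None
        )
        cells["midpoint"] = 2023.0
        Xg = builder.transform(cells, np.full(n_cells, 2023.0))
        cells["true_cum_log_rr"] = Xg.to_numpy() @ beta_vec
        out["cells"] = cells
        out["X_cells"] = Xg
    return out
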