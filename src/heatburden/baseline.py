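"""Stage 3a: grid-cell daily baseline deaths D_g for the hottest months.

The chain: country annual mortality rates 2000-2019 are interpolated with a
natural cubic spline to the analysis year (the natural tail extrapolates
linearly); multiplied by cell population to give annual deaths; cells with
fewer than one annual death are excluded; the hottest-month share of annual
deaths comes from an OLS regression of the observed hottest-month death ratio
on annual mean temperature, annual temperature range, region, climate zone and
log GDP per capita, fitted on the location series; and D_g is the predicted
hottest-month deaths divided by the number of calendar days in the cell's
hottest months.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .heatwave import hottest_month_days, hottest_months
from .splines import natural_spline_interpolate
from .synthetic import LocationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "interpolate_rate",
    "DeathRatioModel",
    "fit_death_ratio_model",
    "grid_daily_baseline",
]


def interpolate_rate(
    years: np.ndarray, rates: np.ndarray, target_year: int = 2023
) -> float:
    """Annual mortality rate at ``target_year`` by natural-spline interpolation
    through the observed (year, rate) pairs; linear beyond the data range
    (the natural-spline tail), floored at 0.  Falls back to a linear trend
    with a warning when fewer than 4 years are observed."""
    years = np.asarray(years, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if years.size < 4:
        warnings.warn(
            f"only {years.size} observed years; falling back to linear trend",
            stacklevel=2,
        )
        if years.size == 1:
            return float(max(rates[0], 0.0))
        slope, intercept = np.polyfit(years, rates, 1)
        return float(max(slope * target_year + intercept, 0.0))
    val = natural_spline_interpolate(years, rates, float(target_year))
    return float(max(val, 0.0))


class DeathRatioModel:
    """OLS model of the hottest-month death ratio on meta-predictors."""

    PREDICTORS = ("annual_mean_temp", "annual_temp_range")

    def __init__(self, clip: tuple[float, float] = (0.05, 0.95)):
        self.clip = clip

    def fit(self, table: pd.DataFrame) -> "DeathRatioModel":
        """``table`` holds one row per location-year with columns ``ratio``,
        the numeric predictors, ``region`` and ``climate_zone`` and
        ``gdp_per_capita``."""
        X = self._design(table, fit=True)
        self.result_ = sm.OLS(table["ratio"].to_numpy(), X).fit()
        return self

    def predict(self, meta: pd.DataFrame) -> np.ndarray:
        X = self._design(meta, fit=False)
        pred = self.result_.predict(X)
        return np.clip(pred, *self.clip)

    def _design(self, df: pd.DataFrame, fit: bool) -> np.ndarray:
        if fit:
            self.region_levels_ = sorted(df["region"].unique())
            self.zone_levels_ = sorted(df["climate_zone"].unique())
        cols = [np.ones(len(df))]
        for lvl in self.region_levels_[1:]:
            cols.append((df["region"] == lvl).to_numpy(dtype=float))
        for lvl in self.zone_levels_[1:]:
            cols.append((df["climate_zone"] == lvl).to_numpy(dtype=float))
        cols.append(df["annual_mean_temp"].to_numpy(dtype=float))
        cols.append(df["annual_temp_range"].to_numpy(dtype=float))
        cols.append(np.log(df["gdp_per_capita"].to_numpy(dtype=float)))
        return np.column_stack(cols)


def location_year_ratios(locations: list[LocationSeries]) -> pd.DataFrame:
    """Observed hottest-month / year-round death ratios per location-year.

    Location-years with zero deaths are skipped.  Only full calendar years
    contribute."""
    rows = []
    for loc in locations:
        months = hottest_months(loc.latitude)
        df = pd.DataFrame({"deaths": loc.deaths}, index=loc.dates)
        for year, grp in df.groupby(df.index.year):
            ndays = pd.Timestamp(year=int(year), month=12, day=31).dayofyear
            if len(grp) < ndays:
                continue  # partial year
            total = grp["deaths"].sum()
            if total == 0:
                logger.info("%s %d skipped: zero annual deaths", loc.location_id, year)
                continue
            hot = grp.loc[grp.index.month.isin(months), "deaths"].sum()
            rows.append(
                {
                    "location_id": loc.location_id,
                    "year": int(year),
                    "ratio": hot / total,
                    "region": loc.meta.region,
                    "climate_zone": loc.meta.climate_zone,
                    "gdp_per_capita": loc.meta.gdp_per_capita,
                    "annual_mean_temp": loc.meta.annual_mean_temp,
                    "annual_temp_range": loc.meta.annual_temp_range,
                }
            )
    return pd.DataFrame(rows)


def fit_death_ratio_model(
    locations: list[LocationSeries], clip: tuple[float, float] = (0.05, 0.95)
) -> DeathRatioModel:
    table = location_year_ratios(locations)
    if table.empty:
        raise ValueError("no usable location-years for the death-ratio model")
    return DeathRatioModel(clip=clip).fit(table)


def grid_daily_baseline(
    cells: pd.DataFrame,
    country_rates: pd.DataFrame,
    ratio_model: DeathRatioModel,
    analysis_year: int = 2023,
) -> pd.DataFrame:
    """Per-cell baseline table: interpolated 2023 rate, annual deaths,
    predicted hottest-month death ratio, hottest-month day count and D_g.

    Cells with fewer than one annual death (including zero population) are
    excluded; the number of exclusions is logged.
    """
    rate_2023 = {}
    for c, grp in country_rates.groupby("country_id"):
        rate_2023[c] = interpolate_rate(
            grp["year"].to_numpy(), grp["rate"].to_numpy(), analysis_year
        )
    out = cells.copy()
    out["annual_rate"] = out["country_id"].map(rate_2023)
    if out["annual_rate"].isna().any():
        missing = out.loc[out["annual_rate"].isna(), "country_id"].unique()
        raise ValueError(f"no mortality rates for countries: {sorted(missing)}")
    out["annual_deaths"] = out["annual_rate"] * out["population"]
    included = out["annual_deaths"] >= 1.0
    n_excl = int((~included).sum())
    if n_excl:
        logger.info("excluding %d cells with < 1 annual death", n_excl)
    out = out[included].copy()
    out["death_ratio"] = ratio_model.predict(out)
    out["hot_days_in_year"] = [
        hottest_month_days(lat, analysis_year) for lat in out["lat"]
    ]
    out["D_g"] = out["annual_deaths"] * out["death_ratio"] / out["hot_days_in_year"]
    return out
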