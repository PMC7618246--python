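"""Heatwave exposure definition: thresholds, run detection, day counting,
hottest-month selection and 0.25-to-0.5 degree regridding.

The exposure is binary: a day is a heatwave day iff it belongs to a maximal run
of at least ``min_duration_days`` consecutive days with daily temperature
strictly above the location-specific percentile threshold computed from the
year-round calibration distribution.  "Year-round" means all calendar days of
the calibration span contribute to the quantile, not only warm-season days.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .config import HeatwaveDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "HeatwaveCalendar",
    "percentile_threshold",
    "detect_heatwaves",
    "hottest_months",
    "hottest_month_days",
    "count_heatwave_days",
    "regrid_half_degree",
    "grid_thresholds",
    "grid_heatwave_days",
]

NORTHERN_MONTHS = frozenset({5, 6, 7, 8})
SOUTHERN_MONTHS = frozenset({11, 12, 1, 2})


@dataclass(frozen=True)
class HeatwaveCalendar:
    """Binary heatwave indicator series with the threshold that produced it."""

    dates: pd.DatetimeIndex
    indicator: np.ndarray  # int8 0/1
    threshold: float

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.indicator):
            raise ValueError("dates and indicator length mismatch")


def percentile_threshold(
    tmean: pd.Series,
    defn: HeatwaveDefinition,
) -> float:
    """Empirical percentile threshold over the calibration span.

    ``tmean`` is a daily series indexed by date.  The calibration span is
    clipped from ``defn``; with no span configured the whole series is the
    calibration set.  Linear-interpolation quantile convention (numpy default).
    """
    s = tmean
    if defn.calibration_start is not None:
        s = s[s.index.year >= defn.calibration_start]
    if defn.calibration_end is not None:
        s = s[s.index.year <= defn.calibration_end]
    vals = s.to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("calibration span contains no non-missing temperatures")
    if vals.size < 365:
        msg = f"calibration span has only {vals.size} non-missing days (<365)"
        if defn.allow_short_calibration:
            warnings.warn(msg, stacklevel=2)
        else:
            raise ValueError(msg)
    return float(np.quantile(vals, defn.percentile / 100.0, method="linear"))


def _run_indicator(above: np.ndarray, min_duration: int) -> np.ndarray:
    """Flag elements of maximal True-runs of length >= min_duration."""
    above = np.asarray(above, dtype=bool)
    n = above.size
    out = np.zeros(n, dtype=np.int8)
    if n == 0:
        return out
    # run-length encode
    edges = np.flatnonzero(np.diff(above.astype(np.int8)) != 0) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [n]))
    for s, e in zip(starts, ends):
        if above[s] and (e - s) >= min_duration:
            out[s:e] = 1
    return out


def detect_heatwaves(
    tmean: pd.Series,
    threshold: float,
    defn: HeatwaveDefinition,
) -> HeatwaveCalendar:
    """Apply the strict-exceedance + run-length rule to a contiguous series.

    Missing temperature breaks a run: a day with NaN temperature is never a
    heatwave day and splits any run spanning it.
    """
    dates = pd.DatetimeIndex(tmean.index)
    if len(dates) > 1:
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if np.any(deltas != 1):
            raise ValueError("detect_heatwaves requires contiguous daily dates")
    vals = tmean.to_numpy(dtype=float)
    above = np.where(np.isfinite(vals), vals > threshold, False)
    ind = _run_indicator(above, defn.min_duration_days)
    return HeatwaveCalendar(dates=dates, indicator=ind, threshold=float(threshold))


def hottest_months(latitude: float, cross_year: bool = False) -> frozenset[int]:
    """Hemisphere-dependent hottest-month set.

    Northern hemisphere (latitude >= 0, equator assigned north): May-August.
    Southern hemisphere: November-February.  ``cross_year`` only changes how
    :func:`count_heatwave_days` interprets the southern block, not the set.
    """
    if not (-90.0 <= latitude <= 90.0):
        raise ValueError(f"latitude out of range: {latitude}")
    return frozenset(NORTHERN_MONTHS) if latitude >= 0 else frozenset(SOUTHERN_MONTHS)


def hottest_month_days(latitude: float, year: int) -> int:
    """Number of calendar days in the cell's hottest months of ``year``."""
    months = hottest_months(latitude)
    return int(
        sum(pd.Timestamp(year=year, month=m, day=1).days_in_month for m in months)
    )


def count_heatwave_days(
    cal: HeatwaveCalendar,
    months: frozenset[int],
    year: int,
    cross_year: bool = False,
) -> int:
    """Count heatwave days falling in the given months of the analysis year.

    For the southern block the default keeps all four months inside calendar
    year ``year`` (Jan, Feb, Nov, Dec of the same year); with
    ``cross_year=True`` the block is Nov-Dec of ``year - 1`` plus Jan-Feb of
    ``year``.
    """
    dates = cal.dates
    month = dates.month.values
    yr = dates.year.values
    if cross_year and months == SOUTHERN_MONTHS:
        sel = ((yr == year) & np.isin(month, [1, 2])) | (
            (yr == year - 1) & np.isin(month, [11, 12])
        )
        # required months: Jan/Feb of year and Nov/Dec of year-1
        need_ok = (((yr == year) & np.isin(month, [1, 2])).any()
                   and ((yr == year - 1) & np.isin(month, [11, 12])).any())
    else:
        sel = (yr == year) & np.isin(month, list(months))
        need_ok = all(((yr == year) & (month == m)).any() for m in months)
    if not need_ok:
        raise ValueError(f"calendar does not cover months {sorted(months)} of {year}")
    return int(cal.indicator[sel].sum())


def regrid_half_degree(field: xr.DataArray) -> xr.DataArray:
    """Block-average a 0.25-degree field to 0.5 degrees.

    Each 0.5-degree output cell is the arithmetic mean of the four 0.25-degree
    cells it contains, timestep by timestep; missing children are excluded and
    an all-missing block stays missing.  Latitude/longitude must be aligned so
    blocks of two rows by two columns nest exactly.
    """
    for dim in ("lat", "lon"):
        if dim not in field.dims:
            raise ValueError(f"field lacks dimension {dim!r}")
        coord = field[dim].values
        step = np.diff(coord)
        if field.sizes[dim] % 2 != 0:
            raise ValueError(f"{dim} size must be even for 2x2 block averaging")
        if not np.allclose(step, 0.25, atol=1e-6):
            raise ValueError(f"{dim} spacing is not 0.25 degrees")
        # first cell centre of each 2-block must sit at k*0.5 + 0.125
        offset = (coord[0] - 0.125) % 0.5
        if not (abs(offset) < 1e-6 or abs(offset - 0.5) < 1e-6):
            raise ValueError(
                f"{dim} grid misaligned: 0.5-degree blocks would not nest "
                f"(first centre {coord[0]})"
            )
    out = field.coarsen(lat=2, lon=2, boundary="exact").mean()
    return out


def grid_thresholds(
    tmean: xr.DataArray, defn: HeatwaveDefinition
) -> xr.DataArray:
    """Per-cell percentile thresholds from a (time, lat, lon) daily field."""
    da = tmean
    years = da["time"].dt.year
    if defn.calibration_start is not None:
        da = da.where(years >= defn.calibration_start, drop=True)
    if defn.calibration_end is not None:
        da = da.sel(time=da["time"].dt.year <= defn.calibration_end)
    return da.quantile(defn.percentile / 100.0, dim="time", method="linear").drop_vars(
        "quantile"
    )


def grid_heatwave_days(
    tmean: xr.DataArray,
    thresholds: xr.DataArray,
    defn: HeatwaveDefinition,
    year: int,
    latitudes: np.ndarray | None = None,
    cross_year: bool = False,
) -> xr.DataArray:
    """Heatwave-day counts N_g for every grid cell in the hottest months.

    Runs are detected on the full daily series per cell (so runs straddling a
    month boundary count correctly), then days are filtered to each cell's
    hemisphere-specific hottest months of ``year``.
    """
    time = pd.DatetimeIndex(tmean["time"].values)
    lats = tmean["lat"].values if latitudes is None else np.asarray(latitudes)
    arr = tmean.transpose("time", "lat", "lon").values
    nlat, nlon = arr.shape[1], arr.shape[2]
    thr = thresholds.transpose("lat", "lon").values
    counts = np.zeros((nlat, nlon), dtype=np.int64)
    for i in range(nlat):
        months = hottest_months(float(lats[i]))
        for j in range(nlon):
            cal = HeatwaveCalendar(
                dates=time,
                indicator=_run_indicator(
                    np.where(np.isfinite(arr[:, i, j]), arr[:, i, j] > thr[i, j], False),
                    defn.min_duration_days,
                ),
                threshold=float(thr[i, j]),
            )
            counts[i, j] = count_heatwave_days(cal, months, year, cross_year)
    return xr.DataArray(
        counts,
        coords={"lat": tmean["lat"], "lon": tmean["lon"]},
        dims=("lat", "lon"),
        name="heatwave_days",
    )
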