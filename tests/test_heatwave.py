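"""Exposure definition: thresholds, run detection, counting, regridding."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from heatburden.config import HeatwaveDefinition
from heatburden.heatwave import (
    HeatwaveCalendar,
    count_heatwave_days,
    detect_heatwaves,
    hottest_month_days,
    hottest_months,
    percentile_threshold,
    regrid_half_degree,
)

from conftest import daily_series


def brute_force_indicator(values, threshold, min_duration):
    """Exhaustive run scanner: day-by-day check of every candidate run."""
    n = len(values)
    out = np.zeros(n, dtype=int)
    for s in range(n):
        for e in range(s + min_duration, n + 1):
            window = values[s:e]
            if np.all(np.isfinite(window)) and np.all(window > threshold):
                out[s:e] = 1
            else:
                break
    return out


class TestThreshold:
    def test_constant_series(self):
        s = daily_series(np.full(400, 20.0))
        assert percentile_threshold(s, HeatwaveDefinition()) == 20.0

    @pytest.mark.parametrize(
        "pct,expected", [(95.0, 95.05), (97.5, 97.525)]
    )
    def test_linear_interpolation_convention(self, pct, expected):
        # 1..100, one value per day: sort-and-interpolate gives 1 + q*99
        s = daily_series(np.arange(1.0, 101.0))
        defn = HeatwaveDefinition(percentile=pct, allow_short_calibration=True)
        with pytest.warns(UserWarning, match="<365"):
            thr = percentile_threshold(s, defn)
        assert thr == pytest.approx(expected, abs=1e-12)

    def test_short_calibration_errors_without_flag(self):
        s = daily_series(np.arange(1.0, 101.0))
        with pytest.raises(ValueError, match="<365"):
            percentile_threshold(s, HeatwaveDefinition())

    def test_all_missing_errors(self):
        s = daily_series(np.full(400, np.nan))
        with pytest.raises(ValueError, match="no non-missing"):
            percentile_threshold(s, HeatwaveDefinition())

    def test_calibration_span_ignores_later_data(self):
        rng = np.random.default_rng(0)
        base = rng.normal(15, 5, 400)
        s1 = daily_series(base, start="2000-01-01")
        s2 = daily_series(np.concatenate([base, base + 30.0]), start="2000-01-01")
        defn = HeatwaveDefinition(calibration_start=2000, calibration_end=2000)
        t1 = percentile_threshold(s1[s1.index.year == 2000], defn)
        t2 = percentile_threshold(s2, defn)
        assert t1 == t2


class TestDetection:
    def test_forced_example(self, defn):
        s = daily_series([30, 30, 20, 30, 20])
        cal = detect_heatwaves(s, 25.0, defn)
        assert cal.indicator.tolist() == [1, 1, 0, 0, 0]

    def test_isolated_exceedance_is_not_heatwave(self, defn):
        s = daily_series([20, 30, 20, 20, 30, 20])
        assert detect_heatwaves(s, 25.0, defn).indicator.sum() == 0

    def test_missing_breaks_run(self, defn):
        s = daily_series([30, np.nan, 30, 30, 30])
        cal = detect_heatwaves(s, 25.0, defn)
        assert cal.indicator.tolist() == [0, 0, 1, 1, 1]

    def test_noncontiguous_dates_error(self, defn):
        s = daily_series([30, 30, 30])
        s = s.drop(s.index[1])
        with pytest.raises(ValueError, match="contiguous"):
            detect_heatwaves(s, 25.0, defn)

    def test_strictly_above(self, defn):
        # ties at the threshold are not exceedances
        s = daily_series([25.0, 25.0, 25.0])
        assert detect_heatwaves(s, 25.0, defn).indicator.sum() == 0

    @pytest.mark.parametrize("min_duration", [1, 2, 3, 5])
    def test_against_brute_force_scanner(self, min_duration):
        rng = np.random.default_rng(42)
        defn = HeatwaveDefinition(min_duration_days=min_duration)
        for _ in range(200):
            vals = rng.normal(20, 6, rng.integers(5, 60))
            vals[rng.random(len(vals)) < 0.05] = np.nan
            s = daily_series(vals)
            got = detect_heatwaves(s, 24.0, defn).indicator
            want = brute_force_indicator(vals, 24.0, min_duration)
            np.testing.assert_array_equal(got, want)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        temps=st.lists(st.floats(0, 40, allow_nan=False), min_size=2, max_size=40),
        dur=st.integers(1, 4),
    )
    def test_counts_monotone_in_duration_and_percentile(self, temps, dur):
        s = daily_series(temps)
        d1 = HeatwaveDefinition(min_duration_days=dur)
        d2 = HeatwaveDefinition(min_duration_days=dur + 1)
        n1 = detect_heatwaves(s, 20.0, d1).indicator.sum()
        n2 = detect_heatwaves(s, 20.0, d2).indicator.sum()
        assert n2 <= n1
        # raising the threshold never increases counts
        n3 = detect_heatwaves(s, 25.0, d1).indicator.sum()
        assert n3 <= n1


class TestHottestMonths:
    @pytest.mark.parametrize(
        "lat,expected",
        [(45.0, {5, 6, 7, 8}), (-30.0, {11, 12, 1, 2}), (0.0, {5, 6, 7, 8})],
    )
    def test_hemisphere_rule(self, lat, expected):
        assert hottest_months(lat) == frozenset(expected)

    def test_latitude_bounds(self):
        with pytest.raises(ValueError):
            hottest_months(91.0)

    def test_day_counts_2023(self):
        assert hottest_month_days(45.0, 2023) == 123  # May-Aug
        assert hottest_month_days(-30.0, 2023) == 120  # Jan+Feb+Nov+Dec


class TestCounting:
    def _calendar(self, year=2023, months_on=()):
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        ind = np.isin(idx.month, list(months_on)).astype(np.int8)
        return HeatwaveCalendar(dates=idx, indicator=ind, threshold=0.0)

    def test_all_zero(self):
        cal = self._calendar()
        assert count_heatwave_days(cal, frozenset({5, 6, 7, 8}), 2023) == 0

    def test_full_hot_months_northern(self):
        cal = self._calendar(months_on=(5, 6, 7, 8))
        assert count_heatwave_days(cal, frozenset({5, 6, 7, 8}), 2023) == 123

    def test_missing_months_error(self):
        idx = pd.date_range("2023-01-01", "2023-03-31", freq="D")
        cal = HeatwaveCalendar(
            dates=idx, indicator=np.zeros(len(idx), dtype=np.int8), threshold=0.0
        )
        with pytest.raises(ValueError, match="does not cover"):
            count_heatwave_days(cal, frozenset({5, 6, 7, 8}), 2023)

    def test_against_date_filter_oracle(self):
        rng = np.random.default_rng(3)
        idx = pd.date_range("2022-01-01", "2023-12-31", freq="D")
        for months in ({5, 6, 7, 8}, {11, 12, 1, 2}):
            for _ in range(25):
                ind = (rng.random(len(idx)) < 0.1).astype(np.int8)
                cal = HeatwaveCalendar(dates=idx, indicator=ind, threshold=0.0)
                got = count_heatwave_days(cal, frozenset(months), 2023)
                want = sum(
                    int(v)
                    for d, v in zip(idx, ind)
                    if d.year == 2023 and d.month in months
                )
                assert got == want

    def test_cross_year_southern_block(self):
        idx = pd.date_range("2022-01-01", "2023-12-31", freq="D")
        ind = np.ones(len(idx), dtype=np.int8)
        cal = HeatwaveCalendar(dates=idx, indicator=ind, threshold=0.0)
        south = frozenset({11, 12, 1, 2})
        within = count_heatwave_days(cal, south, 2023, cross_year=False)
        crossing = count_heatwave_days(cal, south, 2023, cross_year=True)
        assert within == 31 + 28 + 30 + 31  # Jan,Feb,Nov,Dec 2023
        assert crossing == 30 + 31 + 31 + 28  # Nov,Dec 2022 + Jan,Feb 2023


class TestRegrid:
    def _field(self, data, lat0=0.125, lon0=0.125):
        nlat, nlon = data.shape[-2:]
        coords = {
            "lat": lat0 + 0.25 * np.arange(nlat),
            "lon": lon0 + 0.25 * np.arange(nlon),
        }
        dims = ("lat", "lon") if data.ndim == 2 else ("time", "lat", "lon")
        if data.ndim == 3:
            coords["time"] = pd.date_range("2023-01-01", periods=data.shape[0])
        return xr.DataArray(data, coords=coords, dims=dims)

    def test_equal_children(self):
        out = regrid_half_degree(self._field(np.full((2, 2), 10.0)))
        assert float(out.values.squeeze()) == 10.0

    def test_block_mean(self):
        out = regrid_half_degree(self._field(np.array([[1.0, 2.0], [3.0, 4.0]])))
        assert float(out.values.squeeze()) == 2.5

    def test_against_block_mean_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(3, 4, 6))
        data[0, 0, 0] = np.nan
        out = regrid_half_degree(self._field(data))
        for t in range(3):
            for i in range(2):
                for j in range(3):
                    block = data[t, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                    want = np.nanmean(block)
                    assert out.values[t, i, j] == pytest.approx(want, nan_ok=True)

    def test_misaligned_grid_errors(self):
        bad = self._field(np.zeros((2, 2)), lat0=0.25)
        with pytest.raises(ValueError, match="misaligned"):
            regrid_half_degree(bad)

    def test_wrong_spacing_errors(self):
        da = xr.DataArray(
            np.zeros((2, 2)),
            coords={"lat": [0.25, 0.75], "lon": [0.25, 0.75]},
            dims=("lat", "lon"),
        )
        with pytest.raises(ValueError, match="not 0.25"):
            regrid_half_degree(da)
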