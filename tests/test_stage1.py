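"""Stage 1: lag basis, design construction, quasi-Poisson IRLS, reduction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from heatburden.config import PipelineConfig, WorldConfig
from heatburden.heatwave import HeatwaveCalendar
from heatburden.splines import natural_spline_basis, natural_spline_interpolate
from heatburden.stage1 import (
    build_design,
    build_lag_basis,
    cumulative_effect,
    fit_location,
    fit_quasipoisson,
    stratify_periods,
)
from heatburden.synthetic import generate_locations


class TestLagBasis:
    def test_shape_and_rank(self):
        b = build_lag_basis(10, 4)
        assert b.basis.shape == (11, 4)
        assert np.linalg.matrix_rank(b.basis) == 4

    def test_constant_in_span(self):
        b = build_lag_basis(10, 4)
        coef, res, *_ = np.linalg.lstsq(b.basis, np.ones(11), rcond=None)
        fitted = b.basis @ coef
        assert np.allclose(fitted, 1.0, atol=1e-10)

    def test_df_exceeding_lag_errors(self):
        with pytest.raises(ValueError):
            build_lag_basis(3, 4)

    def test_reproduces_natural_spline_curve(self):
        # a curve lying in the natural-spline space over the same knots is
        # reproduced exactly by least squares on the basis
        b = build_lag_basis(10, 4)
        lags = np.arange(11.0)
        target = natural_spline_basis(lags, b.knots) @ np.array([0.3, -0.1, 0.05, 0.2])
        coef, *_ = np.linalg.lstsq(b.basis, target, rcond=None)
        assert np.allclose(b.basis @ coef, target, atol=1e-10)

    @pytest.mark.parametrize("max_lag,df", [(14, 4), (21, 4), (10, 6)])
    def test_sensitivity_configurations(self, max_lag, df):
        b = build_lag_basis(max_lag, df)
        assert b.basis.shape == (max_lag + 1, df)
        assert np.linalg.matrix_rank(b.basis) == df


class TestNaturalSplineInterpolation:
    def test_linear_data_linear_tail(self):
        years = np.arange(2000, 2020)
        rates = 0.01 - 0.0001 * (years - 2000)
        got = natural_spline_interpolate(years, rates, 2023.0)
        assert got == pytest.approx(0.01 - 0.0001 * 23, rel=1e-9)

    def test_exact_at_observed_points(self):
        rng = np.random.default_rng(5)
        years = np.arange(2000, 2020)
        rates = 0.01 + rng.normal(0, 0.001, len(years))
        for y, r in zip(years, rates):
            assert natural_spline_interpolate(years, rates, float(y)) == pytest.approx(
                r, abs=1e-10
            )


def _toy_calendar(indicator, start="2021-01-01"):
    idx = pd.date_range(start, periods=len(indicator), freq="D")
    return HeatwaveCalendar(
        dates=idx, indicator=np.asarray(indicator, dtype=np.int8), threshold=0.0
    )


class TestDesign:
    def test_zero_indicator_zero_lag_columns(self):
        basis = build_lag_basis(10, 4)
        cal = _toy_calendar(np.zeros(400, dtype=int))
        X, names, lag_idx, keep = build_design(cal, basis)
        assert np.all(X[:, lag_idx] == 0)

    def test_year_month_factor_coding(self):
        basis = build_lag_basis(10, 4)
        idx = pd.date_range("2020-01-01", "2021-12-31", freq="D")  # 24 months
        cal = _toy_calendar(np.zeros(len(idx), dtype=int), start="2020-01-01")
        X, names, lag_idx, keep = build_design(cal, basis)
        ym = [n for n in names if n.startswith("ym_")]
        assert len(ym) == 23  # 24 levels, first dropped

    def test_lag_columns_match_convolution_oracle(self):
        basis = build_lag_basis(4, 2)
        ind = np.array([0, 1, 1, 0, 0, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0])
        cal = _toy_calendar(ind)
        X, names, lag_idx, keep = build_design(cal, basis)
        # direct convolution on the 15-day toy calendar
        for col, j in enumerate(lag_idx):
            want = np.array(
                [
                    sum(
                        ind[t - l] * basis.basis[l, col]
                        for l in range(basis.max_lag + 1)
                        if t - l >= 0
                    )
                    for t in range(len(ind))
                ]
            )[keep]
            np.testing.assert_allclose(X[:, j], want, atol=1e-12)

    def test_burn_in_rows_dropped(self):
        basis = build_lag_basis(10, 4)
        cal = _toy_calendar(np.zeros(100, dtype=int))
        X, names, lag_idx, keep = build_design(cal, basis)
        assert X.shape[0] == 90
        assert keep.sum() == 90


class TestQuasiPoisson:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(7.0, 500)
        fit = fit_quasipoisson(y, np.ones((500, 1)))
        assert fit["beta"][0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_equidispersed_data_dispersion_near_one(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(5000), rng.normal(size=5000)])
        mu = np.exp(1.0 + 0.3 * X[:, 1])
        y = rng.poisson(mu)
        fit = fit_quasipoisson(y, X)
        assert fit["dispersion"] == pytest.approx(1.0, abs=0.1)

    def test_matches_statsmodels_poisson_ml(self):
        # point estimates equal Poisson ML; only the covariance scales by phi
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(200, 400)
            X = np.column_stack(
                [np.ones(n), rng.normal(size=n), rng.binomial(1, 0.3, n)]
            )
            beta = rng.normal(0, 0.3, 3) + np.array([1.5, 0, 0])
            y = rng.poisson(np.exp(X @ beta))
            ours = fit_quasipoisson(y, X)
            ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            np.testing.assert_allclose(ours["beta"], ref.params, rtol=1e-6, atol=1e-8)
            # covariance ratio is the Pearson dispersion (when >= 1)
            if ours["dispersion"] > 1.0:
                ratio = np.diag(ours["cov"]) / np.diag(ref.cov_params())
                np.testing.assert_allclose(ratio, ours["dispersion"], rtol=1e-4)

    def test_rank_deficiency_names_columns(self):
        n = 100
        x = np.random.default_rng(3).normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = np.random.default_rng(4).poisson(3.0, n)
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fit_quasipoisson(y, X, names=["intercept", "a", "b"])

    def test_dispersion_floored_at_one(self):
        # underdispersed counts: phi estimate below 1 is floored
        y = np.tile([3, 3, 3, 3], 100)
        fit = fit_quasipoisson(y, np.ones((400, 1)))
        assert fit["dispersion"] == 1.0


class TestCumulativeEffect:
    def test_zero_gamma_gives_rr_one(self):
        basis = build_lag_basis(10, 4)
        p = 4
        fit = {"beta": np.zeros(p), "cov": np.eye(p) * 0.0, "converged": True, "dispersion": 1.0}
        est = cumulative_effect(
            fit, basis, np.arange(4), "loc", (2010, 2014), 2012.0, 5
        )
        assert est.theta == 0.0
        assert est.rr == 1.0

    def test_intercept_basis_sums_lags(self):
        # single constant basis column: theta = (max_lag + 1) * gamma
        basis = build_lag_basis(10, 4)
        const_basis = type(basis)(
            max_lag=10, df=1, basis=np.ones((11, 1)), knots=np.array([0.0, 10.0])
        )
        fit = {"beta": np.array([0.01]), "cov": np.zeros((1, 1)), "converged": True, "dispersion": 1.0}
        est = cumulative_effect(fit, const_basis, np.array([0]), "loc", (2010, 2014), 2012.0, 5)
        assert est.theta == pytest.approx(0.11, abs=1e-12)


class TestStratification:
    def test_two_full_periods(self):
        idx = pd.date_range("1973-01-01", "1982-12-31", freq="D")
        periods = [p for p, _ in stratify_periods(idx)]
        assert periods == [(1973, 1977), (1978, 1982)]

    def test_anchoring_of_partial_span(self):
        idx = pd.date_range("1975-01-01", "1976-12-31", freq="D")
        (period, mask), = stratify_periods(idx)
        assert period == (1973, 1977)
        assert (period[0] + period[1]) / 2 == 1975.0
        assert mask.all()

    def test_against_interval_partition_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            y0 = int(rng.integers(1974, 2015))
            y1 = int(y0 + rng.integers(0, 12))
            idx = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
            got = stratify_periods(idx)
            # oracle: assign each day to its anchored 5-year interval
            assign = {}
            for d in idx:
                k = (d.year - 1973) // 5
                assign.setdefault(k, []).append(d)
            assert len(got) == len(assign)
            for (period, mask), k in zip(got, sorted(assign)):
                assert period == (1973 + 5 * k, 1973 + 5 * k + 4)
                assert mask.sum() == len(assign[k])


@pytest.fixture(scope="module")
def one_location():
    cfg = WorldConfig(n_locations=2, start_year=2013, end_year=2019, seed=42)
    return generate_locations(cfg)[0]


class TestLocationFit:

    def test_temperature_shift_invariance(self, one_location):
        # adding a constant to all temperatures shifts the threshold equally,
        # leaving indicator, fits and theta identical
        cfg = PipelineConfig()
        base = fit_location(one_location, cfg)
        shifted = type(one_location)(
            location_id=one_location.location_id,
            dates=one_location.dates,
            tmean=one_location.tmean + 5.0,
            deaths=one_location.deaths,
            meta=one_location.meta,
            latitude=one_location.latitude,
        )
        alt = fit_location(shifted, cfg)
        assert len(base) == len(alt) > 0
        for a, b in zip(base, alt):
            assert a.theta == pytest.approx(b.theta, abs=1e-9)
            assert a.variance == pytest.approx(b.variance, rel=1e-6)

    def test_sensitivity_configs_return_finite_estimates(self, one_location):
        for max_lag, df in [(14, 4), (21, 4), (10, 6)]:
            cfg = PipelineConfig(max_lag=max_lag, lag_df=df)
            ests = fit_location(one_location, cfg)
            assert ests
            assert all(np.isfinite(e.theta) and e.variance > 0 for e in ests)

    def test_inclusion_rules_drop_sparse_periods(self, one_location):
        cfg = PipelineConfig(min_heatwave_days=10**6)
        assert fit_location(one_location, cfg) == []
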