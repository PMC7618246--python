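"""Stage 2: meta-design encoding, REML meta-regression, BLUPs."""

import numpy as np
import pandas as pd
import pytest

from heatburden.stage2 import MetaDesign, MetaRegression
from heatburden.synthetic import generate_reduced_world


def _meta_frame(n, rng, zones=("A", "B", "C"), regions=("R1", "R2")):
    return pd.DataFrame(
        {
            "climate_zone": rng.choice(zones, n),
            "region": rng.choice(regions, n),
            "gdp_per_capita": np.exp(rng.normal(9.5, 0.5, n)),
            "annual_mean_temp": rng.normal(15, 5, n),
            "annual_temp_range": rng.uniform(5, 25, n),
        }
    )


class TestMetaDesign:
    def test_identical_meta_gives_identical_rows(self):
        rng = np.random.default_rng(0)
        meta = _meta_frame(1, rng)
        meta = pd.concat([meta, meta], ignore_index=True)
        X = MetaDesign().fit_transform(meta, np.array([2000.0, 2000.0]))
        np.testing.assert_array_equal(X.iloc[0].to_numpy(), X.iloc[1].to_numpy())

    def test_column_count_formula(self):
        # 1 + (Z-1) + (R-1) + 3 numeric + 1 midpoint + (Z-1) zone x temp + 1
        rng = np.random.default_rng(1)
        for zones, regions in [(("A", "B", "C"), ("R1", "R2")), (("A", "B", "C", "D", "E"), ("R1", "R2", "R3", "R4"))]:
            meta = _meta_frame(300, rng, zones, regions)
            X = MetaDesign().fit_transform(meta, rng.uniform(1990, 2020, 300))
            Z, R = len(zones), len(regions)
            assert X.shape[1] == 1 + (Z - 1) + (R - 1) + 3 + 1 + (Z - 1) + 1

    def test_unseen_level_raises_listing_level(self):
        rng = np.random.default_rng(2)
        d = MetaDesign()
        d.fit(_meta_frame(50, rng, zones=("A", "B")), np.full(50, 2000.0))
        new = _meta_frame(5, rng, zones=("E",))
        with pytest.raises(ValueError, match="E"):
            d.transform(new, np.full(5, 2023.0))

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        meta = _meta_frame(40, rng)
        meta["annual_temp_range"] = 10.0
        with pytest.warns(UserWarning, match="zero-variance"):
            X = MetaDesign(use_interactions=False).fit_transform(
                meta, rng.uniform(1990, 2020, 40)
            )
        assert "annual_temp_range" not in X.columns

    def test_midpoint_centred(self):
        rng = np.random.default_rng(4)
        meta = _meta_frame(60, rng)
        mid = rng.uniform(1990, 2020, 60)
        X = MetaDesign().fit_transform(meta, mid)
        assert X["midpoint"].mean() == pytest.approx(0.0, abs=1e-9)


def dersimonian_laird_tau2(theta, v):
    """Independent method-of-moments estimate of the between-study variance."""
    w = 1.0 / v
    mu_fe = np.sum(w * theta) / np.sum(w)
    q = np.sum(w * (theta - mu_fe) ** 2)
    k = len(theta)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (k - 1)) / denom)


class TestMetaRegression:
    def test_degenerate_all_equal(self):
        # equal theta, equal v, intercept-only: tau2 = 0, beta0 = common theta
        n = 12
        X = np.ones((n, 1))
        y = np.full(n, 0.14)
        v = np.full(n, 0.01)
        m = MetaRegression().fit(X, y, v=v)
        assert m.tau2_ == 0.0
        assert m.coef_[0] == pytest.approx(0.14, abs=1e-10)

    def test_gls_matches_dl_oracle_at_matched_tau2(self):
        # at the DL tau2, the intercept-only GLS mean must equal the classical
        # random-effects inverse-variance weighted mean
        rng = np.random.default_rng(5)
        theta = rng.normal(0.1, 0.08, 30)
        v = rng.uniform(0.002, 0.01, 30)
        tau2 = dersimonian_laird_tau2(theta, v)
        X = np.ones((30, 1))
        m = MetaRegression()
        blocks = [np.array([i]) for i in range(30)]
        beta, *_ = m._gls(X, theta, v, blocks, tau2)
        want = np.sum(theta / (v + tau2)) / np.sum(1.0 / (v + tau2))
        assert beta[0] == pytest.approx(want, abs=1e-12)

    def test_reml_tau2_close_to_truth_on_large_sample(self):
        rng = np.random.default_rng(6)
        n = 2000
        tau = 0.05
        v = np.full(n, 0.0004)
        y = 0.1 + rng.normal(0, tau, n) + rng.normal(0, np.sqrt(v))
        m = MetaRegression().fit(np.ones((n, 1)), y, v=v)
        assert np.sqrt(m.tau2_) == pytest.approx(tau, rel=0.1)

    def test_prediction_variance_nonnegative(self):
        rng = np.random.default_rng(7)
        w = generate_reduced_world(30, rng, n_periods=2)
        m = MetaRegression().fit(
            w["X"],
            w["effects"]["theta"].to_numpy(),
            v=w["effects"]["variance"].to_numpy(),
            groups=w["effects"]["location_id"].to_numpy(),
        )
        Xnew = w["X"].to_numpy() + rng.normal(0, 0.5, w["X"].shape)
        assert np.all(m.predict_var(Xnew) >= 0)

    def test_zero_tau2_blups_equal_fixed_predictions(self):
        rng = np.random.default_rng(8)
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([0.1, 0.02])
        v = np.full(n, 0.01)
        # pure fixed-effect data with no between-location spread
        y = X @ beta + rng.normal(0, 0.002, n)
        groups = np.array([f"g{i}" for i in range(n)])
        m = MetaRegression().fit(X, y, v=v, groups=groups)
        if m.tau2_ == 0.0:
            np.testing.assert_allclose(
                m.blup_predictions(X, groups), m.predict(X), atol=1e-12
            )

    def test_tiny_variance_blup_approaches_raw_estimate(self):
        n = 10
        X = np.ones((n, 1))
        y = np.linspace(-0.1, 0.3, n)
        v = np.full(n, 0.01)
        v[3] = 1e-10
        groups = np.array([f"g{i}" for i in range(n)])
        m = MetaRegression().fit(X, y, v=v, groups=groups)
        blup = m.blup_predictions(X, groups)
        assert blup[3] == pytest.approx(y[3], abs=1e-4)

    def test_shrinkage_inequality(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            w = generate_reduced_world(
                25,
                rng,
                n_periods=1,
                design_kwargs={
                    "use_interactions": False,
                    "use_zones": False,
                    "use_regions": False,
                    "use_midpoint": False,
                },
            )
            m = MetaRegression().fit(
                w["X"],
                w["effects"]["theta"].to_numpy(),
                v=w["effects"]["variance"].to_numpy(),
                groups=w["effects"]["location_id"].to_numpy(),
            )
            fixed = m.predict(w["X"])
            blup = m.blup_predictions(
                w["X"], w["effects"]["location_id"].to_numpy()
            )
            raw = w["effects"]["theta"].to_numpy()
            assert np.all(np.abs(blup - fixed) <= np.abs(raw - fixed) + 1e-10)

    def test_interactions_never_worsen_gls_fit_at_matched_tau2(self):
        # nested-model property of the residual quadratic form on a tau2 grid
        rng = np.random.default_rng(10)
        w = generate_reduced_world(
            40,
            rng,
            n_periods=2,
            design_kwargs={"use_interactions": True, "use_zones": True, "use_regions": True},
        )
        X_full = w["X"]
        inter_cols = [c for c in X_full.columns if "_x_" in c]
        X_red = X_full.drop(columns=inter_cols)
        y = w["effects"]["theta"].to_numpy()
        v = w["effects"]["variance"].to_numpy()
        groups = w["effects"]["location_id"].to_numpy()
        m = MetaRegression()
        from heatburden.stage2 import _block_slices

        blocks = _block_slices(groups)
        for tau2 in [0.0, 1e-4, 1e-3, 1e-2]:
            *_, quad_full, _ = m._gls(X_full.to_numpy(), y, v, blocks, tau2)
            *_, quad_red, _ = m._gls(X_red.to_numpy(), y, v, blocks, tau2)
            assert quad_full <= quad_red + 1e-8

    def test_interactions_explain_heterogeneity_built_on_interactions(self):
        # worlds generated WITH interaction effects: the interaction model
        # absorbs more between-location variance than the main-effects model
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(10):
            w = generate_reduced_world(
                60,
                rng,
                n_periods=2,
                design_kwargs={
                    "use_interactions": True,
                    "use_zones": True,
                    "use_regions": False,
                },
                beta_true={
                    "intercept": 0.14,
                    "annual_mean_temp": 0.004,
                    "meantemp_x_range": 0.002,
                },
                tau=0.01,
            )
            y = w["effects"]["theta"].to_numpy()
            v = w["effects"]["variance"].to_numpy()
            g = w["effects"]["location_id"].to_numpy()
            X_full = w["X"]
            X_red = X_full.drop(columns=[c for c in X_full.columns if "_x_" in c])
            tau_full = MetaRegression().fit(X_full, y, v=v, groups=g).tau2_
            tau_red = MetaRegression().fit(X_red, y, v=v, groups=g).tau2_
            wins += int(tau_full <= tau_red)
        assert wins >= 8

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            MetaRegression().fit(np.ones((3, 1)), np.zeros(3), v=np.array([0.1, 0.0, 0.2]))

    def test_design_column_mismatch_at_predict(self):
        rng = np.random.default_rng(12)
        w = generate_reduced_world(20, rng)
        m = MetaRegression().fit(
            w["X"],
            w["effects"]["theta"].to_numpy(),
            v=w["effects"]["variance"].to_numpy(),
        )
        bad = w["X"].rename(columns={"annual_mean_temp": "wrong"})
        with pytest.raises(ValueError, match="do not match"):
            m.predict(bad)
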