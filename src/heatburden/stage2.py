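"""Stage 2: multilevel random-effects meta-regression of the stage-1
cumulative log relative risks.

Model:  theta_i = x_i' beta + u_{loc(i)} + eps_i,
        u_loc ~ N(0, tau^2)  shared across a location's 5-year periods,
        eps_i ~ N(0, v_i)    with v_i the known stage-1 variance.

The meta-design x_i holds the five location-level meta-predictors (climate
zone, region, log GDP per capita, annual mean temperature, annual temperature
range), the centred period midpoint as a linear time effect, and two
interactions: climate zone x mean temperature, and mean temperature x
temperature range.

tau^2 is estimated by profiled REML (1-D bounded optimisation), beta by
generalised least squares at the REML tau^2, and per-location random effects
by their posterior means (BLUPs).  The estimator follows the scikit-learn
protocol: ``MetaRegression().fit(X, y, v=..., groups=...)`` with fitted
attributes ``coef_``, ``cov_``, ``tau2_``, ``blup_``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

__all__ = ["MetaDesign", "MetaRegression", "fit_meta"]


class MetaDesign:
    """Encode meta-predictors + period midpoint into the stage-2 design row.

    Fit on the estimation sample (records categorical levels, the midpoint
    centring constant, and any zero-variance columns to drop), then transform
    new meta rows — e.g. grid cells — into identically laid-out rows.  An
    unseen categorical level at transform time is an error, never a silent
    fallback.
    """

    def __init__(
        self,
        use_interactions: bool = True,
        use_zones: bool = True,
        use_regions: bool = True,
        gdp_log_scale: bool = True,
        use_midpoint: bool = True,
    ):
        self.use_interactions = use_interactions
        self.use_zones = use_zones
        self.use_regions = use_regions
        self.gdp_log_scale = gdp_log_scale
        self.use_midpoint = use_midpoint

    def fit(self, meta: pd.DataFrame, midpoint: np.ndarray) -> "MetaDesign":
        self.zone_levels_ = sorted(meta["climate_zone"].unique())
        self.region_levels_ = sorted(meta["region"].unique())
        self.midpoint_center_ = float(np.mean(midpoint)) if self.use_midpoint else 0.0
        X = self._build(meta, midpoint)
        keep = [c for c in X.columns if c == "intercept" or X[c].nunique() > 1]
        dropped = [c for c in X.columns if c not in keep]
        if dropped:
            import warnings

            warnings.warn(f"dropping zero-variance design columns: {dropped}", stacklevel=2)
        self.columns_ = keep
        return self

    def transform(self, meta: pd.DataFrame, midpoint: np.ndarray) -> pd.DataFrame:
        self._check_levels(meta)
        X = self._build(meta, midpoint)
        return X[self.columns_]

    def fit_transform(self, meta: pd.DataFrame, midpoint: np.ndarray) -> pd.DataFrame:
        return self.fit(meta, midpoint).transform(meta, midpoint)

    def _check_levels(self, meta: pd.DataFrame) -> None:
        if self.use_zones:
            unseen = set(meta["climate_zone"]) - set(self.zone_levels_)
            if unseen:
                raise ValueError(f"unseen climate zone level(s): {sorted(unseen)}")
        if self.use_regions:
            unseen = set(meta["region"]) - set(self.region_levels_)
            if unseen:
                raise ValueError(f"unseen region level(s): {sorted(unseen)}")

    def _build(self, meta: pd.DataFrame, midpoint: np.ndarray) -> pd.DataFrame:
        n = len(meta)
        cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
        t = meta["annual_mean_temp"].to_numpy(dtype=float)
        r = meta["annual_temp_range"].to_numpy(dtype=float)
        g = meta["gdp_per_capita"].to_numpy(dtype=float)
        if self.use_zones:
            for z in self.zone_levels_[1:]:
                cols[f"zone_{z}"] = (meta["climate_zone"] == z).to_numpy(dtype=float)
        if self.use_regions:
            for rg in self.region_levels_[1:]:
                cols[f"region_{rg}"] = (meta["region"] == rg).to_numpy(dtype=float)
        cols["log_gdp" if self.gdp_log_scale else "gdp"] = (
            np.log(g) if self.gdp_log_scale else g
        )
        cols["annual_mean_temp"] = t
        cols["annual_temp_range"] = r
        if self.use_midpoint:
            cols["midpoint"] = np.asarray(midpoint, dtype=float) - self.midpoint_center_
        if self.use_interactions:
            if self.use_zones:
                for z in self.zone_levels_[1:]:
                    cols[f"zone_{z}_x_meantemp"] = cols[f"zone_{z}"] * t
            cols["meantemp_x_range"] = t * r
        return pd.DataFrame(cols, index=meta.index)


def _block_slices(groups: np.ndarray) -> list[np.ndarray]:
    order = pd.Series(groups)
    return [np.flatnonzero(order.to_numpy() == g) for g in order.unique()]


class MetaRegression(BaseEstimator):
    """Random-effects meta-regression with a location-level random intercept.

    Parameters
    ----------
    tau2_max : upper bound for the REML search (scaled by var(y) if None).
    reml_tol : optimiser tolerance on tau^2.
    """

    def __init__(self, tau2_max: float | None = None, reml_tol: float = 1e-10):
        self.tau2_max = tau2_max
        self.reml_tol = reml_tol

    # -- REML machinery --------------------------------------------------
    @staticmethod
    def _gls(X, y, v, blocks, tau2):
        """GLS quantities for V = diag(v) + tau2 * block-ones.

        Uses Sherman-Morrison per location block:
        V_b^{-1} = D^{-1} - (tau2 / (1 + tau2 * s)) D^{-1} 1 1' D^{-1}.
        Returns (beta, XtVinvX_inv, logdetV, resid_quad, XtVinvX).
        """
        p = X.shape[1]
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        for idx in blocks:
            Xb, yb, vb = X[idx], y[idx], v[idx]
            dinv = 1.0 / (vb + 0.0)
            s = dinv.sum()
            c = tau2 / (1.0 + tau2 * s)
            Xd = Xb * dinv[:, None]
            yd = yb * dinv
            XtVX += Xb.T @ Xd - c * np.outer(Xd.sum(0), Xd.sum(0))
            XtVy += Xd.T @ yb - c * Xd.sum(0) * yd.sum()
            logdet += np.sum(np.log(vb)) + np.log1p(tau2 * s)
        try:
            XtVX_inv = np.linalg.inv(XtVX)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular GLS normal matrix; check for collinear meta-design columns"
            ) from exc
        beta = XtVX_inv @ XtVy
        # residual quadratic form r' Vinv r
        quad = 0.0
        for idx in blocks:
            rb = y[idx] - X[idx] @ beta
            vb = v[idx]
            dinv = 1.0 / vb
            s = dinv.sum()
            c = tau2 / (1.0 + tau2 * s)
            rd = rb * dinv
            quad += rb @ rd - c * rd.sum() ** 2
        return beta, XtVX_inv, logdet, quad, XtVX

    def _neg2_reml(self, tau2, X, y, v, blocks):
        beta, XtVX_inv, logdet, quad, XtVX = self._gls(X, y, v, blocks, tau2)
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        return logdet + logdet_XtVX + quad

    def fit(self, X, y, v=None, groups=None):
        """Fit by profiled REML.

        Parameters
        ----------
        X : (n, p) design (DataFrame or array); include the intercept column.
        y : (n,) stage-1 cumulative log-RRs.
        v : (n,) known within-estimate variances (> 0).
        groups : (n,) location labels; estimates sharing a label share one
            random intercept.  Defaults to one group per row.
        """
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        if v is None:
            raise ValueError("within-estimate variances v are required")
        v = np.asarray(v, dtype=float)
        if np.any(v <= 0):
            raise ValueError("all variances v must be > 0")
        if len(y) < X.shape[1] + 1:
            raise ValueError("need more estimates than design columns")
        groups = np.arange(len(y)) if groups is None else np.asarray(groups)
        blocks = _block_slices(groups)
        hi = self.tau2_max if self.tau2_max is not None else max(float(np.var(y)) * 5.0, 1e-4)
        res = minimize_scalar(
            self._neg2_reml,
            bounds=(0.0, hi),
            args=(X, y, v, blocks),
            method="bounded",
            options={"xatol": self.reml_tol},
        )
        if not res.success:
            raise RuntimeError(f"REML optimisation failed: {res.message}")
        tau2 = float(res.x)
        # the bounded optimiser cannot sit exactly at 0; compare explicitly
        if self._neg2_reml(0.0, X, y, v, blocks) <= res.fun:
            tau2 = 0.0
        beta, XtVX_inv, logdet, quad, _ = self._gls(X, y, v, blocks, tau2)
        self.coef_ = beta
        self.cov_ = (XtVX_inv + XtVX_inv.T) / 2.0
        self.tau2_ = tau2
        self.reml_neg2loglik_ = float(self._neg2_reml(tau2, X, y, v, blocks))
        # BLUPs: u_hat_b = tau2 * 1' V_b^{-1} (y_b - X_b beta)
        blup = {}
        fitted_fixed = X @ beta
        for idx, g in zip(blocks, pd.Series(groups).unique()):
            rb = y[idx] - fitted_fixed[idx]
            dinv = 1.0 / v[idx]
            s = dinv.sum()
            c = tau2 / (1.0 + tau2 * s)
            blup[g] = float(tau2 * ((rb * dinv).sum() - c * s * (rb * dinv).sum()))
        self.blup_ = blup
        self.groups_ = groups
        self.n_obs_ = len(y)
        return self

    def predict(self, X) -> np.ndarray:
        """Fixed-effects prediction x' beta (no BLUP for unobserved units)."""
        X = self._as_array(X)
        return X @ self.coef_

    def predict_var(self, X) -> np.ndarray:
        """Prediction variance x' V_beta x of the fixed-effect linear predictor."""
        X = self._as_array(X)
        return np.einsum("ij,jk,ik->i", X, self.cov_, X)

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_names_in_:
                raise ValueError(
                    "design columns do not match fit: "
                    f"{list(X.columns)} vs {self.feature_names_in_}"
                )
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def blup_predictions(self, X, groups) -> np.ndarray:
        """x' beta + u_hat_loc for observed locations (Fig.-1B-style values)."""
        X = self._as_array(X)
        u = np.array([self.blup_[g] for g in np.asarray(groups)])
        return X @ self.coef_ + u

    def i2_analogue(self, null_model: "MetaRegression") -> float:
        """Share of between-location variance explained relative to a null fit
        (1 - tau2_full / tau2_null); an I^2-style heterogeneity summary."""
        if null_model.tau2_ <= 0:
            return 0.0
        return float(1.0 - self.tau2_ / null_model.tau2_)


def fit_meta(
    effects: pd.DataFrame,
    meta: pd.DataFrame,
    design: MetaDesign | None = None,
) -> tuple[MetaRegression, MetaDesign, pd.DataFrame]:
    """Convenience wrapper: build the design from an effects table (columns
    ``location_id, midpoint, theta, variance``) joined with per-row meta
    predictors, and fit the meta-regression."""
    if design is None:
        design = MetaDesign()
    X = design.fit_transform(meta, effects["midpoint"].to_numpy())
    model = MetaRegression().fit(
        X,
        effects["theta"].to_numpy(),
        v=effects["variance"].to_numpy(),
        groups=effects["location_id"].to_numpy(),
    )
    return model, design, X
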