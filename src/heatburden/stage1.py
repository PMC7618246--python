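"""Stage 1: location x period quasi-Poisson time-series regression.

Each location's daily death counts are regressed on a lag-distributed binary
heatwave term (natural cubic spline over lags 0..max_lag), year-month factor
dummies for seasonality and long-term trend, and day-of-week indicators, in
consecutive 5-year calibration strata.  The fitted lag coefficients are then
reduced to a single cumulative log relative risk theta with variance v: the
multiplicative change in daily mortality per heatwave day, integrated over its
delayed effects.

Quasi-Poisson means Poisson score equations (log link) solved by iteratively
reweighted least squares, with a free dispersion parameter phi estimated from
the Pearson chi-square and scaling the covariance; point estimates coincide
with Poisson maximum likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .heatwave import HeatwaveCalendar, detect_heatwaves, percentile_threshold
from .splines import natural_spline_basis
from .synthetic import LocationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "LagBasis",
    "EffectEstimate",
    "build_lag_basis",
    "build_design",
    "fit_quasipoisson",
    "cumulative_effect",
    "stratify_periods",
    "fit_location",
    "fit_all_locations",
    "RankDeficientError",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; message names suspect columns."""


@dataclass(frozen=True)
class LagBasis:
    """Natural cubic spline basis over integer lags 0..max_lag.

    The first basis column is constant, so a flat lag curve is representable.
    Internal knots are equally spaced on the log(lag+1) scale, concentrating
    flexibility at short lags where delayed mortality effects change fastest.
    """

    max_lag: int
    df: int
    basis: np.ndarray  # (max_lag+1, df)
    knots: np.ndarray

    @property
    def cum_weights(self) -> np.ndarray:
        """c_j = sum_l B[l, j]; theta = c' gamma is the cumulative effect."""
        return self.basis.sum(axis=0)


@dataclass
class EffectEstimate:
    """Cumulative log-RR for one location x period."""

    location_id: str
    period: tuple[int, int]
    midpoint: float
    theta: float
    variance: float
    converged: bool
    n_heatwave_days: int
    dispersion: float = np.nan

    @property
    def rr(self) -> float:
        return float(np.exp(self.theta))


def build_lag_basis(max_lag: int = 10, df: int = 4) -> LagBasis:
    if df < 2:
        raise ValueError(f"df must be >= 2, got {df}")
    if df > max_lag:
        raise ValueError(f"df ({df}) must not exceed max_lag ({max_lag})")
    # df knots total (boundary at 0 and max_lag), internal knots equally
    # spaced on log(lag + 1)
    log_positions = np.linspace(0.0, np.log(max_lag + 1.0), df)
    knots = np.exp(log_positions) - 1.0
    knots[0], knots[-1] = 0.0, float(max_lag)
    lags = np.arange(max_lag + 1, dtype=float)
    B = natural_spline_basis(lags, knots)
    return LagBasis(max_lag=max_lag, df=df, basis=B, knots=knots)


def build_design(
    cal: HeatwaveCalendar,
    basis: LagBasis,
    deaths: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Design matrix for one location-period.

    Columns: intercept; year-month dummies (first level dropped); day-of-week
    dummies (Monday dropped); the df distributed-lag columns
    x_j(t) = sum_l HW(t-l) B[l, j].  The first max_lag rows are dropped since
    their lag history is incomplete.

    Returns (X, column_names, lag_column_index, kept_row_mask).
    """
    dates = cal.dates
    n = len(dates)
    if n <= basis.max_lag:
        raise ValueError("series shorter than max_lag")
    hw = cal.indicator.astype(float)
    lag_cols = np.column_stack(
        [np.convolve(hw, basis.basis[:, j])[:n] for j in range(basis.df)]
    )
    ym = pd.Categorical(dates.strftime("%Y-%m"))
    ym_d = pd.get_dummies(ym, drop_first=True, dtype=float)
    dow = pd.Categorical(dates.dayofweek, categories=range(7))
    dow_d = pd.get_dummies(dow, drop_first=True, dtype=float)
    # a weekday can be absent in very short series; drop its all-zero dummy
    dow_d = dow_d.loc[:, (dow_d != 0).any(axis=0)]
    names = (
        ["intercept"]
        + [f"ym_{c}" for c in ym_d.columns]
        + [f"dow_{c}" for c in dow_d.columns]
        + [f"lag_b{j}" for j in range(basis.df)]
    )
    X = np.column_stack(
        [np.ones(n), ym_d.to_numpy(), dow_d.to_numpy(), lag_cols]
    )
    keep = np.zeros(n, dtype=bool)
    keep[basis.max_lag :] = True
    X = X[keep]
    # a year-month level entirely inside the dropped burn-in leaves an
    # all-zero column; prune it
    nz = (X != 0).any(axis=0)
    lag_start = len(names) - basis.df
    nz[lag_start:] = True  # never prune lag columns (null worlds have HW = 0)
    nz[0] = True
    if not nz.all():
        dropped = [names[k] for k in np.flatnonzero(~nz)]
        logger.warning("dropping empty factor columns: %s", dropped)
        X = X[:, nz]
        names = [nm for nm, ok in zip(names, nz) if ok]
    lag_idx = np.arange(len(names) - basis.df, len(names))
    return X, names, lag_idx, keep


def fit_quasipoisson(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> dict:
    """Log-link Poisson IRLS with Pearson dispersion.

    Returns dict with ``beta``, ``cov`` (= phi * inverse Fisher information),
    ``dispersion`` (floored at 1), ``converged``, ``deviance``, ``n_iter``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be non-negative integer counts")
    mu = np.clip((y + y.mean()) / 2.0, 1e-8, None)
    eta = np.log(mu)
    beta = np.zeros(p)
    dev = _poisson_deviance(y, mu)
    converged = False
    XtWX = None
    for it in range(1, max_iter + 1):
        W = mu
        z = eta + (y - mu) / mu
        Xw = X * W[:, None]
        XtWX = X.T @ Xw
        XtWz = Xw.T @ z
        try:
            beta_new = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError:
            raise RankDeficientError(_rank_message(X, names)) from None
        if not np.all(np.isfinite(beta_new)):
            raise RankDeficientError(_rank_message(X, names))
        beta = beta_new
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        dev_new = _poisson_deviance(y, mu)
        if abs(dev - dev_new) / (abs(dev_new) + 0.1) < tol:
            dev = dev_new
            converged = True
            break
        dev = dev_new
    # guard against a numerically singular normal matrix that solve accepted
    cond = np.linalg.cond(XtWX)
    if cond > 1e12:
        raise RankDeficientError(_rank_message(X, names))
    pearson = float(np.sum((y - mu) ** 2 / mu))
    dof = max(n - p, 1)
    dispersion = max(pearson / dof, 1.0)  # floored at 1
    cov = dispersion * np.linalg.inv(XtWX)
    return {
        "beta": beta,
        "cov": cov,
        "dispersion": dispersion,
        "converged": converged,
        "deviance": float(dev),
        "n_iter": it,
    }


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _rank_message(X: np.ndarray, names: list[str] | None) -> str:
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    bad = s < s.max() * 1e-10
    suspects = []
    if names is not None and bad.any():
        for row in vt[bad]:
            suspects.extend(names[k] for k in np.argsort(-np.abs(row))[:3])
    return "design matrix is rank deficient" + (
        f"; near-collinear columns: {sorted(set(suspects))}" if suspects else ""
    )


def cumulative_effect(
    fit: dict,
    basis: LagBasis,
    lag_idx: np.ndarray,
    location_id: str,
    period: tuple[int, int],
    midpoint: float,
    n_heatwave_days: int,
) -> EffectEstimate:
    """Reduce fitted lag coefficients to theta = c' gamma, v = c' V c."""
    beta, cov = fit["beta"], fit["cov"]
    if len(lag_idx) != basis.df or np.any(lag_idx >= len(beta)):
        raise ValueError("lag coefficients missing from fit")
    gamma = beta[lag_idx]
    Vg = cov[np.ix_(lag_idx, lag_idx)]
    c = basis.cum_weights
    theta = float(c @ gamma)
    var = float(c @ Vg @ c)
    return EffectEstimate(
        location_id=location_id,
        period=period,
        midpoint=midpoint,
        theta=theta,
        variance=var,
        converged=bool(fit["converged"]),
        n_heatwave_days=n_heatwave_days,
        dispersion=fit["dispersion"],
    )


def stratify_periods(
    dates: pd.DatetimeIndex,
    width: int = 5,
    anchor: int = 1973,
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Split a daily series into fixed global strata anchored at ``anchor``
    (1973-1977, 1978-1982, ...).  Returns (period, row_mask) pairs in order."""
    years = dates.year.values
    idx = (years - anchor) // width
    out = []
    for k in sorted(np.unique(idx)):
        start = anchor + k * width
        mask = idx == k
        out.append(((int(start), int(start + width - 1)), mask))
    return out


def fit_location(
    series: LocationSeries,
    config: PipelineConfig,
    basis: LagBasis | None = None,
) -> list[EffectEstimate]:
    """Run the full stage-1 chain for one location.

    Threshold from the calibration span, run detection, 5-year stratification,
    per-stratum inclusion rules (>= ``min_years`` full years of data,
    >= ``min_heatwave_days`` heatwave days, >= ``min_deaths`` total deaths),
    quasi-Poisson fit and reduction to the cumulative log-RR.
    """
    if basis is None:
        basis = build_lag_basis(config.max_lag, config.lag_df)
    s = pd.Series(series.tmean, index=series.dates)
    thr = percentile_threshold(s, config.heatwave)
    cal = detect_heatwaves(s, thr, config.heatwave)
    out: list[EffectEstimate] = []
    for period, mask in stratify_periods(
        series.dates, config.period_width, config.period_anchor
    ):
        sub_cal = HeatwaveCalendar(
            dates=series.dates[mask], indicator=cal.indicator[mask], threshold=thr
        )
        y_all = series.deaths[mask]
        n_hw = int(sub_cal.indicator.sum())
        if mask.sum() < 365 * config.min_years:
            logger.info("%s %s: excluded (<%d full years)", series.location_id, period, config.min_years)
            continue
        if n_hw < config.min_heatwave_days:
            logger.info("%s %s: excluded (%d heatwave days)", series.location_id, period, n_hw)
            continue
        if y_all.sum() < config.min_deaths:
            logger.info("%s %s: excluded (%d deaths)", series.location_id, period, int(y_all.sum()))
            continue
        X, names, lag_idx, keep = build_design(sub_cal, basis)
        y = y_all[keep]
        try:
            fit = fit_quasipoisson(y, X, names)
        except RankDeficientError as exc:
            logger.warning("%s %s: %s", series.location_id, period, exc)
            continue
        est = cumulative_effect(
            fit,
            basis,
            lag_idx,
            series.location_id,
            period,
            midpoint=(period[0] + period[1]) / 2.0,
            n_heatwave_days=n_hw,
        )
        if not est.converged or not np.isfinite(est.variance) or est.variance <= 0:
            logger.warning(
                "%s %s: non-convergent or degenerate fit, excluded", series.location_id, period
            )
            continue
        out.append(est)
    return out


def fit_all_locations(
    locations: list[LocationSeries], config: PipelineConfig
) -> pd.DataFrame:
    """Stage-1 effects table across locations (one row per location-period)."""
    basis = build_lag_basis(config.max_lag, config.lag_df)
    rows = []
    for loc in locations:
        for est in fit_location(loc, config, basis):
            rows.append(
                {
                    "location_id": est.location_id,
                    "period_start": est.period[0],
                    "period_end": est.period[1],
                    "midpoint": est.midpoint,
                    "theta": est.theta,
                    "variance": est.variance,
                    "n_hw_days": est.n_heatwave_days,
                    "converged": est.converged,
                    "dispersion": est.dispersion,
                }
            )
    return pd.DataFrame(rows)
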