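"""Stage 3b: excess deaths, excess-death ratio and rate, with Monte Carlo
empirical confidence intervals.

Cell-level excess deaths follow ED_g = (RR_g - 1) * N_g * D_g, where RR_g is
the grid-predicted cumulative relative risk, N_g the number of heatwave days
in the cell's hottest months, and D_g the daily baseline deaths.  Negative
cell contributions (RR_g < 1) are retained in all sums.  Aggregates per
region and globally:

* excess death ratio  = 100 * ED / (total hottest-month deaths),
* excess death rate   = 1e6 * ED / population,
* regional proportion = 100 * ED_region / ED_global.

Uncertainty: 500 draws of the stage-2 fixed effects from N(beta_hat, V_beta),
re-propagated through RR_g and every aggregate with N_g and D_g held fixed;
the eCI is the 2.5th-97.5th percentile band across draws.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .stage2 import MetaRegression

logger = logging.getLogger(__name__)

__all__ = [
    "excess_deaths_cell",
    "regional_proportions",
    "aggregate",
    "draw_coefficients",
    "monte_carlo_eci",
]


def excess_deaths_cell(rr, n_days, d_daily):
    """ED_g = (RR_g - 1) * N_g * D_g (vectorised; may be negative)."""
    rr = np.asarray(rr, dtype=float)
    n_days = np.asarray(n_days, dtype=float)
    d_daily = np.asarray(d_daily, dtype=float)
    if np.any(n_days < 0) or np.any(d_daily < 0):
        raise ValueError("N_g and D_g must be non-negative")
    return (rr - 1.0) * n_days * d_daily


def regional_proportions(ed_by_region: pd.Series | dict) -> pd.Series:
    """Each region's percentage share of the global excess deaths."""
    s = pd.Series(ed_by_region, dtype=float)
    return 100.0 * s / s.sum()


def _aggregate_point(cells: pd.DataFrame, ed: np.ndarray, by: str) -> pd.DataFrame:
    df = cells[[by, "population", "D_g", "hot_days_in_year", "N_g"]].copy()
    df["ED"] = ed
    df["hot_deaths"] = df["D_g"] * df["hot_days_in_year"]
    g = df.groupby(by, sort=True).agg(
        excess_deaths=("ED", "sum"),
        hot_deaths=("hot_deaths", "sum"),
        population=("population", "sum"),
    )
    total = pd.DataFrame(
        {
            "excess_deaths": [g["excess_deaths"].sum()],
            "hot_deaths": [g["hot_deaths"].sum()],
            "population": [g["population"].sum()],
        },
        index=pd.Index(["global"], name=by),
    )
    out = pd.concat([total, g])
    out["excess_death_ratio_pct"] = 100.0 * out["excess_deaths"] / out["hot_deaths"]
    out["excess_death_rate_per_million"] = 1e6 * out["excess_deaths"] / out["population"]
    out["regional_proportion_pct"] = (
        100.0 * out["excess_deaths"] / out.loc["global", "excess_deaths"]
    )
    return out


def aggregate(cells: pd.DataFrame, by: str = "region") -> pd.DataFrame:
    """BurdenTable point estimates per region plus a ``global`` row.

    ``cells`` must carry columns ``RR_g``, ``N_g``, ``D_g``,
    ``hot_days_in_year``, ``population`` and the grouping column, and every
    cell must be mapped (no missing group labels)."""
    if cells[by].isna().any():
        raise ValueError(f"cells with missing {by!r} mapping")
    ed = excess_deaths_cell(cells["RR_g"], cells["N_g"], cells["D_g"])
    return _aggregate_point(cells, np.asarray(ed), by)


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    sym = (cov + cov.T) / 2.0
    w, V = np.linalg.eigh(sym)
    if w.min() >= 0:
        return sym
    if w.min() < -1e-10 * max(w.max(), 1.0):
        warnings.warn("covariance not PSD; clipping negative eigenvalues", stacklevel=2)
    w = np.clip(w, 0.0, None)
    return V @ np.diag(w) @ V.T


def draw_coefficients(
    model: MetaRegression, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_sim, p) draws of the stage-2 fixed effects."""
    cov = _nearest_psd(model.cov_)
    return rng.multivariate_normal(
        model.coef_, cov, size=n_sim, method="eigh", check_valid="ignore"
    )


def monte_carlo_eci(
    model: MetaRegression,
    cells: pd.DataFrame,
    X_cells: pd.DataFrame | np.ndarray,
    n_sim: int = 500,
    rng: np.random.Generator | None = None,
    by: str = "region",
    levels: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """BurdenTable with empirical confidence intervals.

    For each of ``n_sim`` coefficient draws the whole aggregation is
    recomputed (N_g, D_g fixed); intervals are percentile bands across draws.
    Returns the point-estimate table with ``*_lo`` / ``*_hi`` columns added.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    Xc = X_cells.to_numpy(dtype=float) if isinstance(X_cells, pd.DataFrame) else np.asarray(X_cells)
    point = aggregate(cells, by=by)
    betas = draw_coefficients(model, n_sim, rng)
    theta_draws = Xc @ betas.T  # (n_cells, n_sim)
    w = (cells["N_g"].to_numpy() * cells["D_g"].to_numpy())[:, None]
    ed_draws = (np.exp(theta_draws) - 1.0) * w
    group_keys = pd.Index(point.index)
    hot_deaths = point["hot_deaths"]
    pop = point["population"]
    ed_mat = np.zeros((len(group_keys), n_sim))
    groups = cells[by].to_numpy()
    for k, gname in enumerate(group_keys):
        mask = np.ones(len(cells), dtype=bool) if gname == "global" else groups == gname
        ed_mat[k] = ed_draws[mask].sum(axis=0)
    glob = ed_mat[list(group_keys).index("global")]
    qlo, qhi = levels[0] / 100.0, levels[1] / 100.0
    out = point.copy()
    for name, mat in (
        ("excess_deaths", ed_mat),
        ("excess_death_ratio_pct", 100.0 * ed_mat / hot_deaths.to_numpy()[:, None]),
        ("excess_death_rate_per_million", 1e6 * ed_mat / pop.to_numpy()[:, None]),
        ("regional_proportion_pct", 100.0 * ed_mat / glob[None, :]),
    ):
        out[f"{name}_lo"] = np.quantile(mat, qlo, axis=1)
        out[f"{name}_hi"] = np.quantile(mat, qhi, axis=1)
    return out
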