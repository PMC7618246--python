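"""Attribution of the heatwave burden to human-induced climate change.

Climate-model daily temperature grids are first bias-corrected against the
reference (reanalysis-role) series with additive monthly-climatology deltas —
the same per-cell, per-calendar-month offset applied to both the factual and
the counterfactual series, which preserves their difference exactly.  Heatwave
days are then recomputed per scenario with the main-analysis definition, using
thresholds from the corrected *factual* climate (the counterfactual asks
"same thresholds, different weather").  The contribution rate per aggregation
unit is

    proportion = (ED_factual - ED_counterfactual) / ED_factual,

pooled across climate models by unweighted mean, and multiplied onto the
stage-3 excess deaths to give attributable deaths.  Empirical confidence
intervals extend the burden Monte Carlo: per coefficient draw, one model index
is resampled uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .config import HeatwaveDefinition
from .heatwave import grid_heatwave_days, grid_thresholds
from .stage2 import MetaRegression
from .synthetic import ScenarioPair

logger = logging.getLogger(__name__)

__all__ = [
    "bias_correct",
    "bias_correct_pair",
    "scenario_heatwave_days",
    "scenario_burden",
    "contribution_rate",
    "AttributionResult",
    "attributable_deaths",
]


def monthly_climatology(da: xr.DataArray, span: tuple[int, int]) -> xr.DataArray:
    years = da["time"].dt.year
    sel = da.sel(time=(years >= span[0]) & (years <= span[1]))
    if sel.sizes["time"] == 0:
        raise ValueError(f"no overlap with calibration span {span}")
    return sel.groupby("time.month").mean("time")


def bias_correct(
    series: xr.DataArray,
    model_factual: xr.DataArray,
    reference: xr.DataArray,
    span: tuple[int, int],
) -> xr.DataArray:
    """Additive monthly-climatology correction.

    corrected = series + (reference climatology - model-factual climatology),
    per cell and calendar month over the calibration span.  Passing the
    factual series itself as ``series`` aligns it with the reference; passing
    the counterfactual applies the *same* offsets.
    """
    delta = monthly_climatology(reference, span) - monthly_climatology(
        model_factual, span
    )
    corrected = (series.groupby("time.month") + delta).drop_vars("month")
    return corrected.rename(series.name)


def bias_correct_pair(pair: ScenarioPair, span: tuple[int, int]) -> ScenarioPair:
    """Bias-correct both members of a pair with the factual-derived offsets."""
    fac = bias_correct(pair.factual, pair.factual, pair.reference, span)
    cf = bias_correct(pair.counterfactual, pair.factual, pair.reference, span)
    return ScenarioPair(
        model_id=pair.model_id,
        factual=fac,
        counterfactual=cf,
        reference=pair.reference,
        truth=dict(pair.truth),
    )


def scenario_heatwave_days(
    pair: ScenarioPair,
    defn: HeatwaveDefinition,
    calibration_span: tuple[int, int],
    year: int,
    cross_year: bool = False,
) -> tuple[xr.DataArray, xr.DataArray]:
    """(N_factual, N_counterfactual) per cell, after bias correction, with
    thresholds computed from the corrected factual climate and applied to both
    scenarios."""
    from dataclasses import replace

    corrected = bias_correct_pair(pair, calibration_span)
    defn_cal = replace(
        defn, calibration_start=calibration_span[0], calibration_end=calibration_span[1]
    )
    thresholds = grid_thresholds(corrected.factual, defn_cal)
    n_f = grid_heatwave_days(corrected.factual, thresholds, defn, year, cross_year=cross_year)
    n_cf = grid_heatwave_days(
        corrected.counterfactual, thresholds, defn, year, cross_year=cross_year
    )
    return n_f, n_cf


def _scenario_ed(
    cells: pd.DataFrame, n_days: xr.DataArray, by: str
) -> pd.Series:
    """Aggregate ED per unit (plus 'global') with scenario heatwave days."""
    n = n_days.values[cells["ilat"].to_numpy(), cells["ilon"].to_numpy()]
    ed = (cells["RR_g"].to_numpy() - 1.0) * n * cells["D_g"].to_numpy()
    s = pd.Series(ed).groupby(cells[by].to_numpy()).sum()
    s.loc["global"] = ed.sum()
    return s.sort_index()


def scenario_burden(
    pair: ScenarioPair,
    cells: pd.DataFrame,
    defn: HeatwaveDefinition,
    calibration_span: tuple[int, int],
    year: int,
    by: str = "region",
    cross_year: bool = False,
) -> tuple[pd.Series, pd.Series]:
    """(ED_factual, ED_counterfactual) per aggregation unit for one model.

    ``cells`` must carry RR_g and D_g from the stage-3 chain plus grid indices
    ``ilat``/``ilon`` matching the scenario grids."""
    nlat, nlon = pair.factual.sizes["lat"], pair.factual.sizes["lon"]
    if cells["ilat"].max() >= nlat or cells["ilon"].max() >= nlon:
        raise ValueError("cell grid indices exceed scenario grid geometry")
    n_f, n_cf = scenario_heatwave_days(pair, defn, calibration_span, year, cross_year)
    return _scenario_ed(cells, n_f, by), _scenario_ed(cells, n_cf, by)


def contribution_rate(ed_f, ed_cf):
    """(ED_f - ED_cf) / ED_f; NaN where the factual burden is zero."""
    ed_f = np.asarray(ed_f, dtype=float)
    ed_cf = np.asarray(ed_cf, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ed_f != 0.0, (ed_f - ed_cf) / ed_f, np.nan)
    return out if out.ndim else float(out)


@dataclass
class AttributionResult:
    """Pooled attribution per aggregation unit."""

    table: pd.DataFrame  # per-unit proportions, attributable deaths, eCIs
    per_model: pd.DataFrame  # unit x model contribution rates
    truth: dict = field(default_factory=dict)


def attributable_deaths(
    pairs: list[ScenarioPair],
    cells: pd.DataFrame,
    burden_table: pd.DataFrame,
    model: MetaRegression | None = None,
    X_cells: pd.DataFrame | np.ndarray | None = None,
    defn: HeatwaveDefinition | None = None,
    calibration_span: tuple[int, int] | None = None,
    year: int = 2023,
    by: str = "region",
    n_sim: int = 500,
    rng: np.random.Generator | None = None,
    cross_year: bool = False,
) -> AttributionResult:
    """Full attribution: per-model contribution rates per unit, pooled by
    unweighted mean, multiplied onto the stage-3 excess deaths; optional eCIs
    from the extended Monte Carlo (coefficient draw + uniform model index).
    """
    if defn is None:
        defn = HeatwaveDefinition()
    scen_n = []  # (model_id, N_f, N_cf) as flat arrays over cells
    per_model_rows = {}
    for pair in pairs:
        n_f_da, n_cf_da = scenario_heatwave_days(
            pair, defn, calibration_span, year, cross_year
        )
        ii, jj = cells["ilat"].to_numpy(), cells["ilon"].to_numpy()
        scen_n.append((pair.model_id, n_f_da.values[ii, jj], n_cf_da.values[ii, jj]))
        ed_f = _scenario_ed(cells, n_f_da, by)
        ed_cf = _scenario_ed(cells, n_cf_da, by)
        per_model_rows[pair.model_id] = pd.Series(
            contribution_rate(ed_f.to_numpy(), ed_cf.to_numpy()), index=ed_f.index
        )
    per_model = pd.DataFrame(per_model_rows)
    pooled = per_model.mean(axis=1)

    table = pd.DataFrame(index=per_model.index)
    ed3 = burden_table["excess_deaths"].reindex(table.index)
    table["proportion_pct"] = 100.0 * pooled
    table["attributable_deaths"] = pooled * ed3
    table["attributable_ratio_pct"] = (
        100.0 * table["attributable_deaths"] / burden_table["hot_deaths"].reindex(table.index)
    )

    if model is not None and X_cells is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        from .burden import draw_coefficients  # noqa: PLC0415

        Xc = (
            X_cells.to_numpy(dtype=float)
            if isinstance(X_cells, pd.DataFrame)
            else np.asarray(X_cells)
        )
        betas = draw_coefficients(model, n_sim, rng)
        model_idx = rng.integers(0, len(scen_n), size=n_sim)
        d_g = cells["D_g"].to_numpy()
        groups = cells[by].to_numpy()
        units = list(table.index)
        attr_draws = np.zeros((len(units), n_sim))
        rrm1 = np.exp(Xc @ betas.T) - 1.0  # (n_cells, n_sim)
        ed3_cell = rrm1 * (cells["N_g"].to_numpy() * d_g)[:, None]
        for m, (_, n_f, n_cf) in enumerate(scen_n):
            cols = np.flatnonzero(model_idx == m)
            if cols.size == 0:
                continue
            ed_f_cell = rrm1[:, cols] * (n_f * d_g)[:, None]
            ed_cf_cell = rrm1[:, cols] * (n_cf * d_g)[:, None]
            for k, unit in enumerate(units):
                mask = (
                    np.ones(len(cells), dtype=bool)
                    if unit == "global"
                    else groups == unit
                )
                ef = ed_f_cell[mask].sum(axis=0)
                ec = ed_cf_cell[mask].sum(axis=0)
                e3 = ed3_cell[mask][:, cols].sum(axis=0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    prop = np.where(ef != 0.0, (ef - ec) / ef, np.nan)
                attr_draws[k, cols] = prop * e3
        table["attributable_deaths_lo"] = np.nanquantile(attr_draws, 0.025, axis=1)
        table["attributable_deaths_hi"] = np.nanquantile(attr_draws, 0.975, axis=1)
    return AttributionResult(table=table, per_model=per_model)
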