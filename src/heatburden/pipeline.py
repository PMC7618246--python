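"""End-to-end pipeline orchestration.

``run_pipeline`` executes: synthetic world -> heatwave exposure -> stage-1
distributed-lag fits -> stage-2 meta-regression -> grid baseline mortality ->
burden with Monte Carlo eCIs -> attribution against the scenario pairs, and
writes stage outputs plus a manifest (config hash, seed, package version) to a
run directory.  All randomness flows from the single root seed, split per
stage, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import attributable_deaths
from .baseline import fit_death_ratio_model, grid_daily_baseline
from .burden import monte_carlo_eci
from .config import PipelineConfig, spawn_rngs
from .heatwave import grid_heatwave_days, grid_thresholds
from .io import save_meta_model, write_manifest
from .stage1 import fit_all_locations
from .stage2 import MetaDesign, MetaRegression
from .synthetic import generate_grid_world, generate_locations, generate_scenarios

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "validate_inputs", "PipelineResult"]


class PipelineResult(dict):
    """Dict of stage outputs with attribute access."""

    __getattr__ = dict.__getitem__


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def locations_meta_frame(locations) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "location_id": [l.location_id for l in locations],
            "latitude": [l.latitude for l in locations],
            "climate_zone": [l.meta.climate_zone for l in locations],
            "region": [l.meta.region for l in locations],
            "gdp_per_capita": [l.meta.gdp_per_capita for l in locations],
            "annual_mean_temp": [l.meta.annual_mean_temp for l in locations],
            "annual_temp_range": [l.meta.annual_temp_range for l in locations],
        }
    )


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    config.validate()
    rngs = spawn_rngs(config.seed, 6)
    world_cfg = replace(config.world, heatwave=config.heatwave)

    # --- synthetic inputs -------------------------------------------------
    locations = generate_locations(world_cfg, rngs[0])
    grid = generate_grid_world(
        world_cfg,
        rngs[1],
        allowed_zones=sorted({l.meta.climate_zone for l in locations}),
        allowed_regions=sorted({l.meta.region for l in locations}),
    )
    pairs = generate_scenarios(world_cfg, grid)

    # --- stage 1 ----------------------------------------------------------
    effects = fit_all_locations(locations, config)
    if effects.empty:
        raise RuntimeError("no location-period passed the stage-1 inclusion rules")
    loc_meta = locations_meta_frame(locations)
    eff_meta = effects.merge(loc_meta, on="location_id", how="left")

    # --- stage 2 ----------------------------------------------------------
    design = MetaDesign(
        use_interactions=config.use_interactions, gdp_log_scale=config.gdp_log_scale
    )
    X = design.fit_transform(eff_meta, eff_meta["midpoint"].to_numpy())
    meta_model = MetaRegression().fit(
        X,
        eff_meta["theta"].to_numpy(),
        v=eff_meta["variance"].to_numpy(),
        groups=eff_meta["location_id"].to_numpy(),
    )

    # --- exposure on the grid --------------------------------------------
    defn_cal = replace(
        config.heatwave,
        calibration_start=world_cfg.calibration_years[0],
        calibration_end=world_cfg.calibration_years[1],
    )
    thresholds = grid_thresholds(grid.tmean, defn_cal)
    n_g = grid_heatwave_days(
        grid.tmean,
        thresholds,
        config.heatwave,
        world_cfg.analysis_year,
        cross_year=config.southern_months_cross_year,
    )

    # --- baseline mortality ----------------------------------------------
    ratio_model = fit_death_ratio_model(locations, clip=config.ratio_clip)
    cells = grid_daily_baseline(
        grid.cells, grid.country_rates, ratio_model, world_cfg.analysis_year
    )
    cells["N_g"] = n_g.values[cells["ilat"].to_numpy(), cells["ilon"].to_numpy()]

    # --- stage-3 prediction + burden --------------------------------------
    X_cells = design.transform(
        cells, np.full(len(cells), float(world_cfg.analysis_year))
    )
    cells["theta_hat"] = meta_model.predict(X_cells)
    cells["RR_g"] = np.exp(cells["theta_hat"])
    burden_table = monte_carlo_eci(
        meta_model,
        cells,
        X_cells,
        n_sim=config.n_sim,
        rng=rngs[2],
        by="region",
    )

    # --- attribution -------------------------------------------------------
    attribution = attributable_deaths(
        pairs,
        cells,
        burden_table,
        model=meta_model,
        X_cells=X_cells,
        defn=config.heatwave,
        calibration_span=world_cfg.calibration_years,
        year=world_cfg.analysis_year,
        n_sim=config.n_sim,
        rng=rngs[3],
        cross_year=config.southern_months_cross_year,
    )
    burden_out = burden_table.join(
        attribution.table, how="left"
    )

    result = PipelineResult(
        locations=locations,
        grid=grid,
        pairs=pairs,
        effects=effects,
        meta_model=meta_model,
        design=design,
        cells=cells,
        burden=burden_out,
        attribution=attribution,
        thresholds=thresholds,
        n_g=n_g,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        effects.to_csv(outdir / "stage1_effects.csv", index=False)
        save_meta_model(meta_model, design, outdir / "stage2_model")
        cells.drop(columns=["theta_hat"]).to_csv(outdir / "cells.csv", index=False)
        burden_out.to_csv(outdir / "burden_table.csv")
        attribution.per_model.to_csv(outdir / "attribution_per_model.csv")
        write_manifest(
            outdir / "manifest.json",
            {
                "config_hash": _config_hash(config),
                "seed": config.seed,
                "heatburden_version": __version__,
                "n_locations": len(locations),
                "n_effects": len(effects),
                "n_cells_included": len(cells),
            },
        )
        config.to_yaml(outdir / "config.yaml")
    return result


def validate_inputs(
    grid=None, locations=None, tmean_quarter=None
) -> list[dict]:
    """Input validation report: a list of findings, each with ``severity``
    (fatal/warning) and ``message``.  An empty list means a clean bundle."""
    findings: list[dict] = []
    if grid is not None:
        lat, lon = grid.lat, grid.lon
        for name, coord in (("lat", lat), ("lon", lon)):
            if len(coord) > 1 and not np.allclose(np.diff(coord), 0.5, atol=1e-6):
                findings.append(
                    {"severity": "fatal", "message": f"{name} spacing is not 0.5 degrees"}
                )
        time = pd.DatetimeIndex(grid.tmean["time"].values)
        if len(time) > 1:
            gaps = np.diff(time.values).astype("timedelta64[D]").astype(int)
            if (gaps != 1).any():
                findings.append(
                    {"severity": "fatal", "message": "grid calendar has gaps"}
                )
        frac_missing = float(np.mean(~np.isfinite(grid.tmean.values)))
        if frac_missing > 0.05:
            findings.append(
                {
                    "severity": "warning",
                    "message": f"{frac_missing:.1%} of grid temperatures missing",
                }
            )
        known = set(grid.country_rates["country_id"])
        unmapped = sorted(set(grid.country_id.ravel()) - known)
        if unmapped:
            findings.append(
                {
                    "severity": "fatal",
                    "message": f"cells mapped to countries without rates: {unmapped}",
                }
            )
    if tmean_quarter is not None:
        from .heatwave import regrid_half_degree

        try:
            regrid_half_degree(tmean_quarter.isel(time=slice(0, 1)) if "time" in tmean_quarter.dims else tmean_quarter)
        except ValueError as exc:
            findings.append({"severity": "fatal", "message": f"regrid: {exc}"})
    if locations is not None:
        for loc in locations:
            d = loc.dates
            if len(d) > 1:
                gaps = np.diff(d.values).astype("timedelta64[D]").astype(int)
                if (gaps != 1).any():
                    findings.append(
                        {
                            "severity": "fatal",
                            "message": f"{loc.location_id}: date gaps",
                        }
                    )
    return findings
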