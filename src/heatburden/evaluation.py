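"""Study-level evaluation experiments.

Each function runs one self-contained parameter-recovery or arithmetic
experiment end to end — generating its inputs, running the pipeline stages,
and measuring the result — and returns a small dict of named quantities.
They back both the acceptance test suite and ``scripts/acceptance.py``.

Problem sizes are the package's reference study conditions: 100 locations x
10 years for first-stage recovery, 140 locations (~420 location-periods) for
the null calibration, 100 replicate reduced worlds for stage-2 coverage, 200
reduced worlds x 200 draws for interval coverage, and 20 constructed worlds
for attribution recovery.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import published
from .burden import aggregate, excess_deaths_cell, monte_carlo_eci, regional_proportions
from .config import PipelineConfig, WorldConfig
from .attribution import attributable_deaths, contribution_rate
from .heatwave import grid_heatwave_days, grid_thresholds, hottest_month_days
from .stage1 import fit_all_locations
from .stage2 import MetaRegression
from .synthetic import (
    constructed_scenario_pair,
    generate_grid_world,
    generate_locations,
    generate_reduced_world,
    generate_scenarios,
)

__all__ = [
    "table1_proportions",
    "stage1_recovery",
    "stage1_null_rejection",
    "stage2_coverage",
    "eci_coverage",
    "attribution_recovery",
    "attribution_null",
]


# ---------------------------------------------------------------------------
# published-table arithmetic
# ---------------------------------------------------------------------------


def table1_proportions() -> dict[str, float]:
    """Recompute the derived proportions of the published burden table from
    its printed central estimates, using the package's aggregation and
    contribution-rate operations."""
    shares = regional_proportions(published.EXCESS_DEATHS)
    out = {
        f"regional_proportion_{k.lower()}_pct": round(float(v), 2)
        for k, v in shares.items()
    }
    for unit, (attr, ed) in published.ATTRIBUTABLE.items():
        # proportion attributable = contribution rate of the attributable part
        prop = contribution_rate(ed, ed - attr)
        key = unit.lower().replace(" ", "_")
        out[f"attributable_proportion_{key}_pct"] = round(100.0 * float(prop), 2)
    return out


# ---------------------------------------------------------------------------
# stage-1 recovery and null calibration
# ---------------------------------------------------------------------------


def stage1_recovery(
    seed: int, n_locations: int = 100, true_rr: float = 1.15
) -> dict[str, float]:
    """Mean estimated cumulative log-RR across location-periods in a world
    with known true cumulative RR."""
    world = WorldConfig(
        n_locations=n_locations,
        start_year=2010,
        end_year=2019,
        true_cum_log_rr=float(np.log(true_rr)),
        seed=seed,
    )
    effects = fit_all_locations(generate_locations(world), PipelineConfig())
    return {
        "mean_theta": float(effects["theta"].mean()),
        "true_theta": float(np.log(true_rr)),
        "n": int(len(effects)),
    }


def stage1_null_rejection(seed: int, n_locations: int = 140) -> dict[str, float]:
    """Empirical size of the nominal-5% Wald test |theta|/sqrt(v) > 1.96 in a
    null world (true cumulative RR = 1, no meta-predictor effects)."""
    world = WorldConfig(
        n_locations=n_locations,
        start_year=2010,
        end_year=2019,
        true_cum_log_rr=0.0,
        meta_effect_coefs={},
        seed=seed,
    )
    effects = fit_all_locations(generate_locations(world), PipelineConfig())
    z = effects["theta"].abs() / np.sqrt(effects["variance"])
    return {"rejection_rate": float((z > 1.96).mean()), "n": int(len(effects))}


# ---------------------------------------------------------------------------
# stage-2 coverage and BLUP shrinkage
# ---------------------------------------------------------------------------


def stage2_coverage(
    seed: int, n_worlds: int = 100, n_locations: int = 50
) -> dict[str, float]:
    """Per-coefficient 2-SE coverage of the meta-regression across replicate
    reduced worlds, plus the BLUP shrinkage inequality on single-estimate
    worlds."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    hits = None
    shrink_ok = 0
    shrink_total = 0
    for _ in range(n_worlds):
        w = generate_reduced_world(n_locations, rng, n_periods=2)
        model = MetaRegression().fit(
            w["X"],
            w["effects"]["theta"].to_numpy(),
            v=w["effects"]["variance"].to_numpy(),
            groups=w["effects"]["location_id"].to_numpy(),
        )
        se = np.sqrt(np.diag(model.cov_))
        ok = np.abs(model.coef_ - w["beta_true"]) <= 2.0 * se
        hits = ok.astype(int) if hits is None else hits + ok
        # shrinkage: single estimate per location
        w1 = generate_reduced_world(
            n_locations // 2,
            rng,
            n_periods=1,
            design_kwargs={
                "use_interactions": False,
                "use_zones": False,
                "use_regions": False,
                "use_midpoint": False,
            },
        )
        m1 = MetaRegression().fit(
            w1["X"],
            w1["effects"]["theta"].to_numpy(),
            v=w1["effects"]["variance"].to_numpy(),
            groups=w1["effects"]["location_id"].to_numpy(),
        )
        fixed = m1.predict(w1["X"])
        blup = m1.blup_predictions(w1["X"], w1["effects"]["location_id"].to_numpy())
        raw = w1["effects"]["theta"].to_numpy()
        tol = 1e-10
        shrink_ok += int(np.all(np.abs(blup - fixed) <= np.abs(raw - fixed) + tol))
        shrink_total += 1
    coverage = hits / n_worlds
    return {
        "min_coef_coverage": float(coverage.min()),
        "mean_coef_coverage": float(coverage.mean()),
        "coef_names": None,
        "shrinkage_fraction": shrink_ok / shrink_total,
        "n_worlds": n_worlds,
    }


# ---------------------------------------------------------------------------
# eCI coverage
# ---------------------------------------------------------------------------


def eci_coverage(
    seed: int,
    n_worlds: int = 200,
    n_locations: int = 20,
    n_draws: int = 200,
    n_cells: int = 60,
) -> dict[str, float]:
    """Fraction of reduced worlds whose 95% eCI for the global excess deaths
    contains the truth (true coefficients pushed through the same grid)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    hit = 0
    for _ in range(n_worlds):
        w = generate_reduced_world(n_locations, rng, n_periods=2, n_cells=n_cells)
        model = MetaRegression().fit(
            w["X"],
            w["effects"]["theta"].to_numpy(),
            v=w["effects"]["variance"].to_numpy(),
            groups=w["effects"]["location_id"].to_numpy(),
        )
        cells = w["cells"].copy()
        cells["region"] = "all"
        cells["N_g"] = rng.poisson(12.0, size=len(cells)).astype(float)
        cells["D_g"] = np.exp(rng.normal(0.7, 0.5, size=len(cells)))
        cells["hot_days_in_year"] = 123.0
        cells["population"] = 1e5
        true_ed = float(
            np.sum(
                excess_deaths_cell(
                    np.exp(cells["true_cum_log_rr"]), cells["N_g"], cells["D_g"]
                )
            )
        )
        cells["RR_g"] = np.exp(model.predict(w["X_cells"]))
        table = monte_carlo_eci(
            model, cells, w["X_cells"], n_sim=n_draws, rng=rng, by="region"
        )
        lo = table.loc["global", "excess_deaths_lo"]
        hi = table.loc["global", "excess_deaths_hi"]
        hit += int(lo <= true_ed <= hi)
    return {"coverage": hit / n_worlds, "n_worlds": n_worlds}


# ---------------------------------------------------------------------------
# attribution recovery
# ---------------------------------------------------------------------------

_EPISODES_STRONG = {"p_start": 0.067, "p_persist": 0.65, "boost_range": (7.0, 9.0)}


def _attribution_cells(world, grid_n_g) -> pd.DataFrame:
    """Stage-3 cell table from generator truth (true RR, true death ratio)."""
    cells = world.cells.copy()
    cells["RR_g"] = np.exp(cells["true_cum_log_rr"])
    cells["annual_deaths"] = cells["true_rate_2023"] * cells["population"]
    cells = cells[cells["annual_deaths"] >= 1.0].copy()
    cells["hot_days_in_year"] = [
        hottest_month_days(lat, 2023) for lat in cells["lat"]
    ]
    cells["D_g"] = (
        cells["annual_deaths"] * cells["true_death_ratio"] / cells["hot_days_in_year"]
    )
    cells["N_g"] = grid_n_g.values[
        cells["ilat"].to_numpy(), cells["ilon"].to_numpy()
    ].astype(float)
    return cells


def attribution_recovery(seed: int, n_seeds: int = 20) -> dict[str, float]:
    """Pooled attributable proportion on constructed counterfactuals whose
    true attributable fraction is ~0.5 by construction (every second factual
    heatwave run removed)."""
    props = []
    truths = []
    for k in range(n_seeds):
        world_cfg = WorldConfig(
            grid_shape=(8, 8),
            calibration_years=(2021, 2022),
            analysis_year=2023,
            country_block=(4, 4),
            seed=int(np.random.SeedSequence((seed, 4, k)).generate_state(1)[0] % 2**31),
        )
        rng = np.random.default_rng(np.random.SeedSequence((seed, 5, k)))
        world = generate_grid_world(world_cfg, rng, episode_kwargs=_EPISODES_STRONG)
        pair = constructed_scenario_pair(world_cfg, world)
        defn = world_cfg.heatwave
        defn_cal = replace(
            defn,
            calibration_start=world_cfg.calibration_years[0],
            calibration_end=world_cfg.calibration_years[1],
        )
        thr = grid_thresholds(world.tmean, defn_cal)
        n_g = grid_heatwave_days(world.tmean, thr, defn, world_cfg.analysis_year)
        cells = _attribution_cells(world, n_g)
        burden_table = aggregate(cells, by="region")
        res = attributable_deaths(
            [pair],
            cells,
            burden_table,
            defn=defn,
            calibration_span=world_cfg.calibration_years,
            year=world_cfg.analysis_year,
        )
        props.append(res.table.loc["global", "proportion_pct"] / 100.0)
        truths.append(pair.truth["true_fraction_overall"])
    return {
        "mean_proportion": float(np.mean(props)),
        "mean_true_fraction": float(np.mean(truths)),
        "n_seeds": n_seeds,
    }


def attribution_null(seed: int, n_seeds: int = 20) -> dict[str, float]:
    """Mean |pooled proportion| when the warming offset is zero (factual and
    counterfactual share the weather, so the proportion should be exactly 0)."""
    vals = []
    for k in range(n_seeds):
        world_cfg = WorldConfig(
            grid_shape=(6, 6),
            calibration_years=(2021, 2022),
            analysis_year=2023,
            country_block=(3, 3),
            warming_offset_C=0.0,
            n_models=2,
            seed=int(np.random.SeedSequence((seed, 6, k)).generate_state(1)[0] % 2**31),
        )
        rng = np.random.default_rng(np.random.SeedSequence((seed, 7, k)))
        world = generate_grid_world(world_cfg, rng, episode_kwargs=_EPISODES_STRONG)
        pairs = generate_scenarios(world_cfg, world)
        defn_cal = replace(
            world_cfg.heatwave,
            calibration_start=world_cfg.calibration_years[0],
            calibration_end=world_cfg.calibration_years[1],
        )
        thr = grid_thresholds(world.tmean, defn_cal)
        n_g = grid_heatwave_days(
            world.tmean, thr, world_cfg.heatwave, world_cfg.analysis_year
        )
        cells = _attribution_cells(world, n_g)
        burden_table = aggregate(cells, by="region")
        res = attributable_deaths(
            pairs,
            cells,
            burden_table,
            defn=world_cfg.heatwave,
            calibration_span=world_cfg.calibration_years,
            year=world_cfg.analysis_year,
        )
        vals.append(abs(res.table.loc["global", "proportion_pct"] / 100.0))
    return {"mean_abs_proportion": float(np.mean(vals)), "n_seeds": n_seeds}
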