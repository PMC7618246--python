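"""File formats: location series CSV, gridded NetCDF, meta-model bundles.

NetCDF writing picks the first available engine (netcdf4, h5netcdf, scipy);
the scipy engine writes classic NetCDF3, so integer fields are cast to int32
and times encoded as days since an epoch.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .stage2 import MetaDesign, MetaRegression
from .synthetic import LocationSeries, MetaPredictors

__all__ = [
    "write_locations",
    "read_locations",
    "write_netcdf",
    "save_meta_model",
    "load_meta_model",
]


def _nc_engine() -> str:
    for eng in ("netcdf4", "h5netcdf", "scipy"):
        if eng in xr.backends.list_engines():
            return eng
    raise RuntimeError("no NetCDF backend available")


def write_netcdf(obj: xr.DataArray | xr.Dataset, path) -> None:
    ds = obj.to_dataset() if isinstance(obj, xr.DataArray) else obj
    eng = _nc_engine()
    if eng == "scipy":
        ds = ds.copy()
        for name, var in ds.variables.items():
            if var.dtype == np.int64:
                ds[name] = var.astype("int32")
    ds.to_netcdf(path, engine=eng)


def write_locations(locations: list[LocationSeries], outdir) -> None:
    """One CSV per location (date, tmean, deaths) plus a metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for loc in locations:
        loc.frame().to_csv(outdir / f"{loc.location_id}.csv", index=False)
        meta_rows.append(
            {
                "location_id": loc.location_id,
                "latitude": loc.latitude,
                "climate_zone": loc.meta.climate_zone,
                "region": loc.meta.region,
                "gdp_per_capita": loc.meta.gdp_per_capita,
                "annual_mean_temp": loc.meta.annual_mean_temp,
                "annual_temp_range": loc.meta.annual_temp_range,
                "true_cum_log_rr": loc.truth.get("true_cum_log_rr", np.nan),
            }
        )
    pd.DataFrame(meta_rows).to_csv(outdir / "locations_meta.csv", index=False)


def read_locations(outdir) -> list[LocationSeries]:
    outdir = Path(outdir)
    meta = pd.read_csv(outdir / "locations_meta.csv")
    out = []
    for _, row in meta.iterrows():
        df = pd.read_csv(outdir / f"{row.location_id}.csv", parse_dates=["date"])
        out.append(
            LocationSeries(
                location_id=row.location_id,
                dates=pd.DatetimeIndex(df["date"]),
                tmean=df["tmean"].to_numpy(),
                deaths=df["deaths"].to_numpy(dtype=np.int64),
                meta=MetaPredictors(
                    climate_zone=row.climate_zone,
                    region=row.region,
                    gdp_per_capita=row.gdp_per_capita,
                    annual_mean_temp=row.annual_mean_temp,
                    annual_temp_range=row.annual_temp_range,
                ),
                latitude=row.latitude,
                truth={"true_cum_log_rr": row.get("true_cum_log_rr", np.nan)},
            )
        )
    return out


def save_meta_model(model: MetaRegression, design: MetaDesign, outdir) -> None:
    """Serialise a fitted stage-2 model so prediction can run without refit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = {
        "tau2": float(model.tau2_),
        "reml_neg2loglik": float(model.reml_neg2loglik_),
        "columns": model.feature_names_in_,
        "design": {
            "use_interactions": design.use_interactions,
            "use_zones": design.use_zones,
            "use_regions": design.use_regions,
            "gdp_log_scale": design.gdp_log_scale,
            "use_midpoint": design.use_midpoint,
            "zone_levels": list(design.zone_levels_),
            "region_levels": list(design.region_levels_),
            "midpoint_center": float(design.midpoint_center_),
            "columns": list(design.columns_),
        },
    }
    with open(outdir / "meta_model.yaml", "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
    pd.DataFrame({"name": model.feature_names_in_, "coef": model.coef_}).to_csv(
        outdir / "meta_coefficients.csv", index=False
    )
    pd.DataFrame(
        model.cov_, index=model.feature_names_in_, columns=model.feature_names_in_
    ).to_csv(outdir / "meta_covariance.csv")
    pd.Series(model.blup_, name="blup").rename_axis("location_id").to_csv(
        outdir / "meta_blups.csv"
    )


def load_meta_model(outdir) -> tuple[MetaRegression, MetaDesign]:
    outdir = Path(outdir)
    with open(outdir / "meta_model.yaml") as fh:
        spec = yaml.safe_load(fh)
    coefs = pd.read_csv(outdir / "meta_coefficients.csv")
    cov = pd.read_csv(outdir / "meta_covariance.csv", index_col=0)
    blups = pd.read_csv(outdir / "meta_blups.csv", index_col=0)["blup"]
    model = MetaRegression()
    model.feature_names_in_ = list(coefs["name"])
    model.coef_ = coefs["coef"].to_numpy()
    model.cov_ = cov.to_numpy()
    model.tau2_ = spec["tau2"]
    model.reml_neg2loglik_ = spec["reml_neg2loglik"]
    model.blup_ = blups.to_dict()
    d = spec["design"]
    design = MetaDesign(
        use_interactions=d["use_interactions"],
        use_zones=d["use_zones"],
        use_regions=d["use_regions"],
        gdp_log_scale=d["gdp_log_scale"],
        use_midpoint=d["use_midpoint"],
    )
    design.zone_levels_ = d["zone_levels"]
    design.region_levels_ = d["region_levels"]
    design.midpoint_center_ = d["midpoint_center"]
    design.columns_ = d["columns"]
    return model, design


def write_manifest(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
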