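"""Configuration objects shared across the pipeline.

Two configuration families live here:

* :class:`HeatwaveDefinition` — the exposure definition (percentile threshold,
  minimum run length, temperature metric, calibration span) applied identically
  to station-like series and to gridded fields.
* :class:`WorldConfig` — parameters of the synthetic world generator, including
  the ground-truth quantities (cumulative log relative risk, lag weight curve,
  warming offset, climate-model bias) that downstream recovery tests compare
  against.
* :class:`PipelineConfig` — the bundle of per-stage settings consumed by the
  end-to-end pipeline runner, serialisable to/from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "HeatwaveDefinition",
    "WorldConfig",
    "PipelineConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass(frozen=True)
class HeatwaveDefinition:
    """Percentile-and-duration heatwave definition.

    A heatwave day is a day belonging to a run of at least ``min_duration_days``
    consecutive days whose daily temperature (``metric``) lies strictly above
    the location-specific ``percentile`` of the year-round temperature
    distribution over the calibration span.
    """

    percentile: float = 95.0
    min_duration_days: int = 2
    metric: str = "mean"  # one of {"mean", "min", "max"}
    calibration_start: int | None = None  # calendar years; None = full series
    calibration_end: int | None = None
    allow_short_calibration: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 100.0):
            raise ConfigError(f"percentile must be in (0, 100), got {self.percentile}")
        if self.min_duration_days < 1:
            raise ConfigError(
                f"min_duration_days must be >= 1, got {self.min_duration_days}"
            )
        if self.metric not in {"mean", "min", "max"}:
            raise ConfigError(f"metric must be mean/min/max, got {self.metric!r}")


def _default_lag_weights() -> tuple[float, ...]:
    # geometric decay over lags 0..10, normalised; smooth enough for a
    # 4-df natural-spline lag basis to represent almost exactly
    w = 0.7 ** np.arange(11)
    return tuple(w / w.sum())


def _default_meta_coefs() -> dict[str, float]:
    # per-unit shifts of the true cumulative log-RR around its population value;
    # features are centred at their sampling means inside the generator
    return {
        "annual_mean_temp": 0.004,
        "annual_temp_range": -0.003,
        "log_gdp": -0.015,
        "mean_temp_x_range": 0.0004,
    }


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world, including its ground truth."""

    n_locations: int = 100
    start_year: int = 2010
    end_year: int = 2019
    true_cum_log_rr: float = float(np.log(1.15))
    lag_weights: tuple[float, ...] = field(default_factory=_default_lag_weights)
    meta_effect_coefs: dict[str, float] = field(default_factory=_default_meta_coefs)
    dispersion: float = 1.3
    baseline_deaths_per_day: float = 30.0
    grid_shape: tuple[int, int] = (10, 12)
    grid_lat_start: float = -3.0  # cell-centre latitude of first row (0.5 deg step)
    grid_lon_start: float = 10.0
    calibration_years: tuple[int, int] = (2015, 2019)
    analysis_year: int = 2023
    n_models: int = 4
    warming_offset_C: float = 1.0
    model_bias_C: float = 1.5
    heatwave: HeatwaveDefinition = field(default_factory=HeatwaveDefinition)
    country_block: tuple[int, int] = (4, 4)  # grid cells per synthetic country
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ConfigError(f"n_locations must be >= 2, got {self.n_locations}")
        if self.dispersion < 1.0:
            raise ConfigError(f"dispersion must be >= 1, got {self.dispersion}")
        if self.baseline_deaths_per_day <= 0:
            raise ConfigError("baseline_deaths_per_day must be positive")
        w = np.asarray(self.lag_weights, dtype=float)
        if w.size != 11 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ConfigError(
                "lag_weights must be 11 non-negative reals summing to 1 (tol 1e-12)"
            )
        if self.grid_shape[0] * self.grid_shape[1] <= 0:
            raise ConfigError(f"grid_shape has zero cells: {self.grid_shape}")
        if self.warming_offset_C < 0:
            raise ConfigError("warming_offset_C must be >= 0")
        if self.end_year < self.start_year:
            raise ConfigError("end_year before start_year")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults mirror the main analysis
    (95th percentile / >=2-day heatwaves on daily mean temperature, 10-day lag
    with a 4-df natural cubic spline, 5-year calibration strata, 500 Monte
    Carlo draws)."""

    heatwave: HeatwaveDefinition = field(default_factory=HeatwaveDefinition)
    max_lag: int = 10
    lag_df: int = 4
    period_width: int = 5
    period_anchor: int = 1973
    min_years: int = 2
    min_heatwave_days: int = 10
    min_deaths: int = 100
    use_interactions: bool = True
    gdp_log_scale: bool = True
    ratio_clip: tuple[float, float] = (0.05, 0.95)
    southern_months_cross_year: bool = False
    n_sim: int = 500
    seed: int = 0
    world: WorldConfig = field(default_factory=WorldConfig)

    def validate(self) -> None:
        if self.lag_df < 2:
            raise ConfigError("lag_df must be >= 2")
        if self.max_lag < self.lag_df:
            raise ConfigError("max_lag must be >= lag_df")
        if self.n_sim < 2:
            raise ConfigError("n_sim must be >= 2")
        lo, hi = self.ratio_clip
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"ratio_clip bounds invalid: {self.ratio_clip}")

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)
                }
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        return conv(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "heatwave" in d and isinstance(d["heatwave"], dict):
            d["heatwave"] = HeatwaveDefinition(**d["heatwave"])
        if "world" in d and isinstance(d["world"], dict):
            w = dict(d["world"])
            for key in ("lag_weights", "grid_shape", "calibration_years", "country_block"):
                if key in w and isinstance(w[key], list):
                    w[key] = tuple(w[key])
            if "heatwave" in w and isinstance(w["heatwave"], dict):
                w["heatwave"] = HeatwaveDefinition(**w["heatwave"])
            if "meta_effect_coefs" in w and w["meta_effect_coefs"] is not None:
                w["meta_effect_coefs"] = dict(w["meta_effect_coefs"])
            d["world"] = WorldConfig(**w)
        if "ratio_clip" in d and isinstance(d["ratio_clip"], list):
            d["ratio_clip"] = tuple(d["ratio_clip"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def spawn_rngs(seed: int, n: int) -> Sequence[np.random.Generator]:
    """Split one root seed into ``n`` independent generators (one per stage)."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
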