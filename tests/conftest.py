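import numpy as np
import pandas as pd
import pytest

from heatburden.config import HeatwaveDefinition, WorldConfig
from heatburden.synthetic import generate_grid_world, generate_locations


@pytest.fixture(scope="session")
def small_world_cfg() -> WorldConfig:
    return WorldConfig(
        n_locations=8,
        start_year=2015,
        end_year=2019,
        seed=7,
        grid_shape=(6, 8),
        country_block=(3, 4),
    )


@pytest.fixture(scope="session")
def small_locations(small_world_cfg):
    return generate_locations(small_world_cfg)


@pytest.fixture(scope="session")
def small_grid(small_world_cfg):
    return generate_grid_world(small_world_cfg)


@pytest.fixture()
def defn() -> HeatwaveDefinition:
    return HeatwaveDefinition()


def daily_series(values, start="2020-01-01") -> pd.Series:
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=idx)
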