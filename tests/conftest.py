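import numpy as np
import pandas as pd
import pytest

from paqikit import (
    GridField,
    GridTransform,
    SimConfig,
    StationTable,
    ZoneMask,
    sample_stations,
    simulate_fields,
)


@pytest.fixture
def transform():
    return GridTransform(100.0, 45.0, 0.1, -0.1)


@pytest.fixture
def grid_factory(transform):
    """Build a GridField from an array (and optional mask) on the shared grid."""

    def make(values, mask=None, name="var", t=transform):
        values = np.asarray(values, float)
        if mask is None:
            mask = np.ones(values.shape, bool)
        return GridField(values=values, mask=np.asarray(mask, bool), transform=t, name=name)

    return make


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(shape=(24, 24), n_stations=120, n_zones=4, seed=11)


@pytest.fixture(scope="session")
def small_fields(small_config):
    return simulate_fields(small_config)


@pytest.fixture(scope="session")
def small_stations(small_config, small_fields):
    return sample_stations(small_fields, small_config)


@pytest.fixture
def station_table_factory():
    """StationTable from a predictor matrix and target vector."""

    def make(X, y, names=None, pollutant="PM2.5"):
        X = np.asarray(X, float)
        n, p = X.shape
        names = names or [f"x{j}" for j in range(p)]
        frame = pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(n)],
                "lat": np.linspace(30, 40, n),
                "lon": np.linspace(100, 110, n),
                "pollutant": pollutant,
                "observed_pm": np.asarray(y, float),
            }
        )
        for j, name in enumerate(names):
            frame[name] = X[:, j]
        return StationTable(frame, names)

    return make


@pytest.fixture
def two_cell_zone(transform):
    """1x2 grid with PM (10, 100), population (3, 1), one zone."""
    pm = GridField(np.array([[10.0, 100.0]]), np.ones((1, 2), bool), transform, name="pm")
    pop = GridField(np.array([[3.0, 1.0]]), np.ones((1, 2), bool), transform, name="pop")
    zones = ZoneMask(np.array([[1, 1]]), {1: "A"}, transform)
    return pm, pop, zones
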