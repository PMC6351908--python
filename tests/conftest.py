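import numpy as np
import pytest

from lapmd.fixtures import ToyCitySpec, make_inventory_params, make_landuse, make_met
from lapmd.grids import Grid
from lapmd.meteorology import WindRose


@pytest.fixture(scope="session")
def toy_spec() -> ToyCitySpec:
    return ToyCitySpec(nrows=40, ncols=40, seed=7)


@pytest.fixture(scope="session")
def toy_city(toy_spec):
    grid, landuse, dem = make_landuse(toy_spec)
    return {
        "spec": toy_spec,
        "grid": grid,
        "landuse": landuse,
        "dem": dem,
        "met": make_met(toy_spec),
        "params": make_inventory_params(toy_spec, "reference"),
        "params_target": make_inventory_params(toy_spec, "target"),
    }


@pytest.fixture
def flat_grid() -> Grid:
    return Grid(nrows=21, ncols=21, cellsize=300.0)


@pytest.fixture
def uniform_rose() -> WindRose:
    """Equal-frequency rose with 3 m/s in every sector, neutral stability."""
    return WindRose(
        frequency=np.full(8, 1 / 8),
        mean_speed=np.full(8, 3.0),
        stability=("D",) * 8,
    )
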