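import numpy as np
import pytest

from enmtransfer.raster import RasterGrid
from enmtransfer.world import ChangeScenario, WorldConfig, make_world


@pytest.fixture
def flat_grid():
    """A 10x10 grid of zeros with 100 m cells, origin at (0, 1000)."""
    return RasterGrid(np.zeros((10, 10)), 100.0, (0.0, 1000.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_world():
    """A small two-epoch world with the default change scenario."""
    cfg = WorldConfig(fine_shape=(30, 30))
    return make_world(cfg, seed=7)


@pytest.fixture(scope="session")
def frozen_world():
    """Same landscape, no environmental change between epochs."""
    cfg = WorldConfig(
        fine_shape=(30, 30),
        change=ChangeScenario(
            tmax_delta=0.0, tmin_delta=0.0, prec_delta=0.0,
            encroachment_rate=0.0, n_fires=0,
        ),
    )
    return make_world(cfg, seed=7)
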