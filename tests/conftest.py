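import numpy as np
import pytest

from polarscape.gridio import DEMGrid
from polarscape.synth import default_truth, generate_bundle, generate_dem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=0)


@pytest.fixture(scope="session")
def small_dem():
    return generate_dem(32, 32, cellsize=100.0, relief=800.0, smoothness=3.0, seed=1)


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(n_sites=60, seed=7, dem_shape=(32, 32), cellsize=150.0)


def plane_dem(nrows=12, ncols=12, cellsize=10.0, sx=0.0, sy=0.0, base=100.0):
    """Inclined-plane DEM: z = base + sx*x + sy*y (x east, y north)."""
    cols = np.arange(ncols)
    rows = np.arange(nrows)
    x = (cols + 0.5) * cellsize
    y = (nrows - rows - 0.5) * cellsize
    xx, yy = np.meshgrid(x, y)
    return DEMGrid(base + sx * xx + sy * yy, cellsize=cellsize)


@pytest.fixture
def make_plane():
    return plane_dem
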