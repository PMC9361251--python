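import numpy as np
import pytest

from fuelscape.grids import GridSpec
from fuelscape.lidar import NormalizedCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec20():
    """Small 20-m grid, 10x10 cells."""
    return GridSpec(xmin=0.0, ymax=200.0, cell=20.0, nrows=10, ncols=10)


def make_cloud(rng, n=1000, extent=200.0, max_h=30.0):
    """Random normalized cloud with a mix of ground and vegetation returns."""
    x = rng.uniform(0, extent, n)
    y = rng.uniform(0, extent, n)
    h = np.where(rng.uniform(size=n) < 0.3, 0.0, rng.uniform(0, max_h, n))
    cls = np.where(h == 0, 2, 1)
    return NormalizedCloud(x=x, y=y, z=h + 100.0, height=h, classification=cls)


@pytest.fixture
def random_cloud(rng):
    return make_cloud(rng)
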