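import numpy as np
import pytest
from hypothesis import settings

from dsmspread.geometry import Domain, SwarmMap

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def small_domain() -> Domain:
    """A 50 x 50 cell (500 m) village-scale raster."""
    return Domain(origin=(0.0, 0.0), extent=(500.0, 500.0), cell_size=10.0)


@pytest.fixture
def two_swarms() -> SwarmMap:
    return SwarmMap(np.array([[240.0, 260.0], [320.0, 200.0]]), sigma=30.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210916)
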