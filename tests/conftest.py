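import numpy as np
import pytest

from threatscape.grid import GridSpec, RasterLayer


@pytest.fixture
def grid10():
    """Small 10x10 grid of 5-km cells, NW origin at (0, 50 km)."""
    return GridSpec(n_rows=10, n_cols=10, origin_x=0.0, origin_y=50_000.0, cell_size=5000.0)


@pytest.fixture
def constant_layer(grid10):
    def make(value: float, name: str = "const") -> RasterLayer:
        return RasterLayer(grid10, np.full(grid10.shape, value), name=name)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
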