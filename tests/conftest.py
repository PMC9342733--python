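import numpy as np
import pytest

from aquaniche.grid import GridSpec

from helpers import make_layer


@pytest.fixture
def grid30():
    return GridSpec(resolution_arcmin=30)


@pytest.fixture
def small_grid():
    """A 10x10-degree working extent at 30 arcmin (20x20 cells)."""
    return GridSpec(resolution_arcmin=30, lat_min=0.0, lat_max=10.0, lon_min=0.0, lon_max=10.0)


@pytest.fixture
def constant_layers(small_grid):
    """One constant layer per raster catalog variable, value = 10 * (index+1)."""
    from aquaniche.environment import RASTER_VARIABLE_IDS

    return [
        make_layer(vid, lambda lon, lat, v=10.0 * (i + 1): np.full_like(lon, v), small_grid)
        for i, vid in enumerate(RASTER_VARIABLE_IDS)
    ]
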