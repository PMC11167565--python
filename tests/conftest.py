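import numpy as np
import pytest

from thyromap.raster import AtlasGrid, Mask


@pytest.fixture
def rng():
    return np.random.default_rng(20240524)


@pytest.fixture
def small_grid():
    """Small front-view atlas grid for fast pixel-level tests."""
    return AtlasGrid("front", (-1.0, 1.0), (-1.0, 1.0), 0.02)


def random_mask(rng, grid, density=0.3, specimen_id="r"):
    px = rng.random(grid.shape) < density
    return Mask(px, grid.resolution, grid.view, specimen_id, grid)


@pytest.fixture
def identity_front_landmarks():
    """Axis-aligned landmark pixels: border along row 100, midline along col 200."""
    return {
        "upper_border": [(100.0, 100.0), (300.0, 100.0)],
        "midline": [(200.0, 50.0), (200.0, 300.0)],
    }
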