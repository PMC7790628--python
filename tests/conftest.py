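import logging

import numpy as np
import pytest

from bharal.grid import Grid

logging.getLogger("bharal").setLevel(logging.ERROR)


def make_plane(nrows=20, ncols=20, cell=30.0, gx=0.0, gy=0.0, z0=1000.0):
    """Analytic plane z = z0 + gx*x + gy*y on a grid (y = north)."""
    g = Grid(np.zeros((nrows, ncols)), origin=(0.0, nrows * cell), cell_size=cell)
    X, Y = g.cell_centers()
    return g.like(z0 + gx * X + gy * Y)


@pytest.fixture
def plane():
    return make_plane


@pytest.fixture
def rugged_dem():
    """A small smooth random DEM for oracle comparisons."""
    from scipy import ndimage

    rng = np.random.default_rng(7)
    z = ndimage.gaussian_filter(rng.standard_normal((50, 50)), 3.0)
    z = 4000 + 400 * (z - z.min()) / (z.max() - z.min())
    return Grid(z, origin=(0.0, 50 * 30.0), cell_size=30.0)
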