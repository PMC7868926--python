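import numpy as np
import pytest

from biofilmscape.dem_io import DEMGrid
from biofilmscape.synthetic_data import gen_hydraulic_profile


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def slab_grid():
    """Uniform 0.3 mm slab, 20x20 px at 40 um pixels."""
    return DEMGrid(heights=np.full((20, 20), 0.3))


@pytest.fixture
def hydraulic_profile():
    return gen_hydraulic_profile()


def make_grid(heights, **kwargs):
    return DEMGrid(heights=np.asarray(heights, dtype=float), **kwargs)
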