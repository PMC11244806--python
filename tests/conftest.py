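import numpy as np
import pytest

from vstain import datapipe as dp
from vstain import phantom as ph


@pytest.fixture(scope="session")
def small_phantom():
    """A 64-voxel cube phantom shared by read-only tests."""
    cfg = ph.PhantomConfig(shape=(64, 64, 64), n_cells=24, cell_diameter=18,
                           attenuation_depth=32.0, attenuation_width=6.0, seed=7)
    return ph.generate_phantom(cfg)


@pytest.fixture(scope="session")
def flat_phantom():
    """A shallow phantom used for 2D patch studies."""
    cfg = ph.PhantomConfig(shape=(32, 96, 96), n_cells=20, cell_diameter=20,
                           attenuation_depth=16.0, attenuation_width=4.0, seed=11)
    return ph.generate_phantom(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
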