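import numpy as np
import pytest

from v1mt.params import ModelParams
from v1mt.stimulus import BarSpec, GridSpec, make_bar_stimulus


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bar_stim():
    """Short 45-deg bar drifting right on a small grid (fast to simulate)."""
    bar = BarSpec(orientation=45, direction="right", length=9, bar_width=1,
                  n_frames=6)
    return make_bar_stimulus(bar, GridSpec(32, 32))


@pytest.fixture
def random_field(rng):
    """Random activity field in [0, 1] on a small grid."""
    return rng.random((8, 8, 8))
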