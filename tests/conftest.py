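import numpy as np
import pytest

from topofcs import OpticalModel, make_flat, make_random_field, make_sinusoid
from topofcs.surface_model import interpolate_surface


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def optics():
    return OpticalModel()


@pytest.fixture(scope="session")
def flat_surface():
    """Small flat patch (2x2 um) interpolated to the fine grid."""
    return interpolate_surface(make_flat(17, 17, 125.0), 5.0)


@pytest.fixture(scope="session")
def rough_surface():
    """Random-field patch (2x2 um, 150 nm RMS, 400 nm correlation length)."""
    hmap = make_random_field(17, 17, 125.0, rms=150.0, correlation_length=400.0, seed=7)
    return interpolate_surface(hmap, 5.0)


@pytest.fixture(scope="session")
def sinusoid_map():
    return make_sinusoid(64, 64, 125.0, amplitude=100.0, period=1000.0)
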