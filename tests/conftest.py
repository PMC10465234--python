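import numpy as np
import pytest

from opmtheta import forward, synth


@pytest.fixture(scope="session")
def head():
    return forward.HeadModel()


@pytest.fixture(scope="session")
def opm_array():
    return synth.build_array("opm_triaxial")


@pytest.fixture(scope="session")
def squid_array():
    return synth.build_array("squid_radial")


@pytest.fixture(scope="session")
def coarse_grid(head, opm_array):
    """8 mm lead-field grid shared by the heavier beamformer tests."""
    return forward.build_leadfield_grid(head, opm_array, 0.008)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
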