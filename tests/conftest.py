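import numpy as np
import pytest

from mbtrack.rheology import HCT_PRESETS
from mbtrack.vasculature import build_idealized_aaa, lubrication_flow, make_waveform


@pytest.fixture(scope="session")
def geometry_mesh():
    return build_idealized_aaa()


@pytest.fixture(scope="session")
def geometry(geometry_mesh):
    return geometry_mesh[0]


@pytest.fixture(scope="session")
def mesh(geometry_mesh):
    return geometry_mesh[1]


@pytest.fixture(scope="session")
def neg_waveform():
    return make_waveform("negative", 0.44, 1.0)


@pytest.fixture(scope="session")
def flow(geometry, neg_waveform):
    return lubrication_flow(geometry, neg_waveform, HCT_PRESETS[45])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
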