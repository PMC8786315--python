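import numpy as np
import pytest

from cryonano import ChannelGeometry, ScatteringCalibration, SyntheticSpec


@pytest.fixture
def geom():
    return ChannelGeometry(width_nm=750, max_height_nm=100, length_um=50, n_channels=5)


@pytest.fixture
def cal():
    return ScatteringCalibration()


@pytest.fixture
def clean_spec():
    """Noiseless synthetic conditions for exact round trips."""
    return SyntheticSpec(seed=0, noise_model="none")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
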