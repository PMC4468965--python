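import numpy as np
import pytest

from noisereg.noise_model import NoiseFloorParams
from noisereg.synthetic_data import SyntheticSpec


@pytest.fixture
def floor_params():
    """Study floor parameters: extrinsic 0.025, burst 450, background 100."""
    return NoiseFloorParams(0.025, 450.0, 100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec():
    return SyntheticSpec(seed=12345)
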