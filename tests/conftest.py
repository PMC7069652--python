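import numpy as np
import pytest

from hsibg.core import WavelengthGrid
from hsibg.correction import NormalizedSourceProfile
from hsibg.synthesis import SpectrumLibrary, SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def grid100():
    return WavelengthGrid.linspace(450.0, 900.0, 100)


@pytest.fixture
def grid300():
    return WavelengthGrid.linspace(450.0, 900.0, 300)


@pytest.fixture
def library100(grid100):
    return SpectrumLibrary.default(grid100)


@pytest.fixture
def ramp_profile(grid100):
    """Source exactly proportional to its min-max normalisation (min = 0),
    for which the retrieval is exact on every unclamped channel."""
    ramp = np.linspace(0.0, 1.0, grid100.count)
    return NormalizedSourceProfile.from_source(ramp, grid100)


@pytest.fixture
def small_cfg():
    """Desk-scale study conditions used across the classification tests."""
    return SynthConfig(shape=(64, 128), n_channels=100, n_train=10, n_test=3, seed=1)
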