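import numpy as np
import pytest

from mpcest import bmc
from mpcest.presets import default_pulse, get_preset


@pytest.fixture
def pulse():
    """Canonical saturation: 2 uT, 2 s, 7 T."""
    return default_pulse(offset_ppm=1.2)


@pytest.fixture
def water_brain():
    return bmc.ExchangePool.water(1.9, 0.0443)


@pytest.fixture
def brain():
    return get_preset("brain")


@pytest.fixture
def tumor():
    return get_preset("tumor")


@pytest.fixture
def dge_offsets():
    return np.array([-2.0, -1.5, -1.2, -0.9, 0.0, 0.9, 1.2, 1.5, 2.0])
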