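import pytest

from taueq.design import DiameterRange
from taueq.hydraulics import CULTURE_MEDIUM

LUMEN_LENGTH = 1.1e-2  # m, the standard channel length


@pytest.fixture
def medium():
    """Culture medium with 2% serum at 37 °C (μ = 0.79 mPa·s)."""
    return CULTURE_MEDIUM


@pytest.fixture
def target_range():
    """The lumen-diameter range the board is optimized for: 180–300 µm."""
    return DiameterRange(180e-6, 300e-6)
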