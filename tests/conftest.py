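import numpy as np
import pytest

from metacascade import CascadeParams


@pytest.fixture
def ladder5():
    """Fig-style geometric ladder (1/5)^i with m=3 levels."""
    return CascadeParams.geometric(0.2, 3)


@pytest.fixture
def ladder_half_m3():
    return CascadeParams.geometric(0.5, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
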