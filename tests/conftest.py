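import numpy as np
import pytest

from patternfit.imaging import PatternImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    return PatternImage(rng.uniform(0.0, 1.0, size=(64, 64)))


@pytest.fixture
def grating():
    """Horizontal sinusoidal grating with wavelength 16 px on a 128 grid."""
    n = 128
    x = np.arange(n)
    img = 0.5 + 0.5 * np.sin(2 * np.pi * x / 16.0)
    return PatternImage(np.tile(img, (n, 1)))
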