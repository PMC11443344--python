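import numpy as np
import pytest
from hypothesis import settings

from chillgrade.synthetic import make_leaf_image

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def clean_image():
    """Noise-free synthetic leaf with a moderate injury fraction."""
    return make_leaf_image(seed=11, target_lk=0.20, size=(64, 64), noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_image():
    """Synthetic leaf at the default noise level."""
    return make_leaf_image(seed=11, target_lk=0.20, size=(64, 64), noise_sd=8.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def random_gray():
    """Random 12x12 grayscale patch with an irregular mask (oracle fixtures)."""
    gen = np.random.default_rng(5)
    gray = gen.integers(0, 256, size=(12, 12)).astype(np.uint8)
    mask = gen.random((12, 12)) < 0.85
    mask[4:8, 4:8] = True
    return gray, mask
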