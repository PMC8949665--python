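import numpy as np
import pytest

from tvnls import Image, add_awgn, make_phantom


@pytest.fixture(scope="session")
def phantom128():
    """Textured 128x128 phantom used across suites."""
    return make_phantom(128, 128, texture_period=8, n_shapes=6, seed=0)


@pytest.fixture(scope="session")
def noisy128(phantom128):
    return add_awgn(phantom128, sigma=20.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_image(rng):
    return Image(rng.uniform(0, 255, size=(16, 16)))
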