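import numpy as np
import pytest

from topoliver.phantom import default_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture
def annulus_3x3():
    """8 border pixels at 0 around a center pixel at 1: one loop at eps=0."""
    img = np.zeros((3, 3))
    img[1, 1] = 1.0
    return img


@pytest.fixture
def two_blob_image():
    """Two isolated dark pixels on a bright background."""
    img = np.ones((5, 5))
    img[1, 1] = 0.0
    img[3, 3] = 0.0
    return img
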