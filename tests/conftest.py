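import numpy as np
import pytest

from memcrowd import Image2D, RegionOfInterest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """A 32x32 noisy STED-like image at 25 nm pixels."""
    return Image2D(rng.gamma(2.0, 5.0, size=(32, 32)), 25.0, channel="test")


@pytest.fixture
def full_roi(random_image):
    return RegionOfInterest.full(random_image)
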