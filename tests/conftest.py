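import numpy as np
import pytest

from petdeconv import ActivityImage, ImageGrid, ReconstructedPET


@pytest.fixture
def grid8():
    return ImageGrid(8, 8, 2.08)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_activity(grid8, rng):
    return ActivityImage(grid8, rng.uniform(0.2, 3.0, size=grid8.shape))


@pytest.fixture
def random_obs(grid8, rng):
    return ReconstructedPET(grid8, rng.uniform(0.2, 3.0, size=grid8.shape))
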