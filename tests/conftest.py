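import numpy as np
import pytest

from lpwave.synthetic import PhantomSpec, make_brain_phantom
from lpwave.wavelets import ImageGrid


@pytest.fixture(scope="session")
def phantom256():
    return make_brain_phantom(PhantomSpec(size=256, seed=1))


@pytest.fixture(scope="session")
def phantom64():
    return make_brain_phantom(PhantomSpec(size=64, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_image(rng):
    return ImageGrid(rng.normal(size=(64, 64)), dynamic_range=1.0)
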