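import numpy as np
import pytest

from texfuse import GrayImage


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20240915))


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.random((16, 16)))


def random_images(seed, n, shape):
    gen = np.random.Generator(np.random.PCG64(seed))
    return [gen.random(shape) for _ in range(n)]
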