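import numpy as np
import pytest

from dicyc.networks import GeneratorSpec, TransformerSpec, build_generator, build_transformer
from dicyc.phantom import PhantomConfig, generate_phantom_pair


TINY_GEN = GeneratorSpec(base_channels=8, resnet_blocks=2)
TINY_TR = TransformerSpec(reducer_channels=16, hidden=32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_image(rng):
    """A smooth standardized 64x64 test image."""
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(rng.normal(size=(64, 64)), 3.0)
    return (img - img.mean()) / img.std()


@pytest.fixture
def tiny_generator():
    return build_generator(TINY_GEN, seed=7)


@pytest.fixture
def tiny_transformer():
    return build_transformer(TINY_TR, latent_channels=TINY_GEN.latent_channels, seed=8)


@pytest.fixture
def phantom_pair():
    return generate_phantom_pair(1, (64, 64), PhantomConfig())
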