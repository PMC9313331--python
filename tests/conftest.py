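import numpy as np
import pytest

from blastoseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """48 px phantoms: smallest size divisible by 16 with >=2 px thick rings."""
    return PhantomConfig(image_size=48, seed=0)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config, 0)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """A handful of 32 px phantoms for fast training smoke tests."""
    cfg = PhantomConfig(image_size=32, seed=7)
    return [generate_phantom(cfg, i) for i in range(8)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
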