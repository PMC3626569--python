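import numpy as np
import pytest

from musclemt import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Default-geometry phantom without speckle, with its ground truth."""
    cfg = PhantomConfig(speckle_scale=0.0)
    img, truth = generate_phantom(cfg, seed=0)
    return cfg, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
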