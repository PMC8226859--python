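import numpy as np
import pytest

from hiproi import SynthConfig, generate_samples


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synth_samples():
    """A small low-resolution synthetic set shared across tests."""
    cfg = SynthConfig(n_images=12, size_profile="low_res", seed=7)
    return generate_samples(cfg)
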