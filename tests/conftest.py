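import numpy as np
import pytest

from noisyseg.synthetic import NoiseSpec, generate_phantom, make_noisy_dataset


@pytest.fixture(scope="session")
def phantom128():
    return generate_phantom(seed=7, size=128, n_trees=3)


@pytest.fixture(scope="session")
def tiny_records():
    """Two small records for fast trainer tests."""
    return make_noisy_dataset(2, NoiseSpec(level="LV2"), seed=3, size=32)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
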