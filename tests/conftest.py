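import numpy as np
import pytest

from rnadivide.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def synth_suite():
    """A moderate synthetic suite shared across tests."""
    return generate_dataset(SynthConfig(), 100, seed=7)


@pytest.fixture(scope="session")
def small_synth_config():
    """Short structures for fast training tests."""
    return SynthConfig(length_range=(150, 300), n_domains_range=(2, 4))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
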