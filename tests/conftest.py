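import numpy as np
import pytest

from morenet import crypto


@pytest.fixture(scope="session")
def config():
    return crypto.EncryptionConfig(rng_seed=1234)


@pytest.fixture(scope="session")
def key(config):
    return crypto.generate_secret_key(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
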