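import numpy as np
import pytest

from periostage.synthetic import SyntheticConfig, generate_case


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticConfig(noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_case(noiseless_config):
    return generate_case(noiseless_config, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
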