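import numpy as np
import pytest

from dcra.datagen import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A small labelled synthetic session shared across tests."""
    return generate_session(SyntheticConfig(n_epochs=60, dim_e=8, dim_o=6, seed=11))


@pytest.fixture(scope="session")
def default_session():
    """Default-dimension session (36/25 features) for end-to-end checks."""
    return generate_session(SyntheticConfig(n_epochs=80, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
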