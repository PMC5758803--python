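import numpy as np
import pytest

from echotune.stimulus import make_protocol
from echotune.synth import synthesize_session


@pytest.fixture(scope="session")
def protocol11():
    """The standard 11-tone, 2–40 kHz rhythmic-train protocol."""
    return make_protocol(11, 2000.0, 40000.0)


@pytest.fixture(scope="session")
def small_bundle():
    """One small synthetic session shared by read-only tests."""
    return synthesize_session(n_neurons=30, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
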