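import logging
import warnings

import numpy as np
import pytest

from sedyn.synthetic import SessionConfig, generate_session

# epoch-edge warnings and dropped-trial logs are expected in bulk runs
logging.getLogger("sedyn").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="Mean of empty slice")


@pytest.fixture(scope="session")
def short_session():
    """One synthetic propofol session long enough for a full LOC-ROC cycle."""
    return generate_session(SessionConfig(seed=11, duration_s=1500.0))


@pytest.fixture(scope="session")
def default_session():
    """A full-length default (propofol, middle-dose) synthetic session."""
    return generate_session(SessionConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
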