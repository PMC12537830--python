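import logging

import numpy as np
import pytest

from synchropipe import emit_session, state_preset

logging.getLogger("synchropipe").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def pd_session():
    """A PD-state ground-truth session (no injection), reused read-only."""
    return emit_session(state_preset("PD", seed=11))


@pytest.fixture(scope="session")
def lid_session():
    """A LID-state ground-truth session with an l-dopa injection."""
    return emit_session(state_preset("LID", seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
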