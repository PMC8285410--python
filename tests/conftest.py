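import numpy as np
import pandas as pd
import pytest

from epimem import synth
from epimem.types import GenerativeParams, SimulationConfig


@pytest.fixture(scope="session")
def small_study():
    """Three-protocol study at reduced size (6 participants) for fast tests."""
    return synth.simulate_study(seed=11, overrides={"n_participants": 6})


@pytest.fixture(scope="session")
def sl_data():
    """One small SL dataset (4 participants)."""
    cfg = SimulationConfig(protocol="SL", seed=5, n_participants=4)
    return synth.simulate_protocol(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def make_source_trials(rows):
    """Source-trial DataFrame from compact tuples:
    (pid, event, is_old, resp, pc, pconf, tc, tconf)."""
    cols = [
        "participant_id",
        "event_id",
        "is_old",
        "object_response",
        "place_correct",
        "place_conf",
        "time_correct",
        "time_conf",
    ]
    return pd.DataFrame(rows, columns=cols)
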