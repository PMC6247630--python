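import numpy as np
import pytest

import smrdecode as sd


@pytest.fixture(scope="session")
def short_protocol() -> sd.TrialProtocol:
    """Two blocks of five trials: 100 s of recording."""
    return sd.TrialProtocol(trials_per_block=5, blocks_per_session=2)


@pytest.fixture(scope="session")
def default_session(short_protocol) -> sd.SessionRecording:
    """Shared drift-free session with the default ERD structure."""
    smr = sd.SmrModel(drift_scale=0.0)
    return sd.generate_session(short_protocol, smr, sd.EmgModel(), seed=101,
                               patient=1, session=1)


@pytest.fixture(scope="session")
def flat_session(short_protocol) -> sd.SessionRecording:
    """Session without any task modulation (d = 0 everywhere)."""
    smr = sd.SmrModel(mu_depth=0.0, beta_depth=0.0, drift_scale=0.0)
    emg = sd.EmgModel(residual_gain=0.0, mirror_gain=0.0)
    return sd.generate_session(short_protocol, smr, emg, seed=102)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
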