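import numpy as np
import pytest

from dbsrecruit import synth
from dbsrecruit.session import align_trials, zscore_traces


@pytest.fixture(scope="session")
def small_session():
    """A compact 2-block session with planted responders of all four classes."""
    cfg = synth.SynthConfig(
        n_neurons=40,
        trials_per_block=8,
        n_blocks=2,
        class_fractions={
            "sustained_excited": (0.0, 0.2),
            "transient_excited": (0.0, 0.1),
            "sustained_inhibited": (0.0, 0.1),
            "transient_inhibited": (0.0, 0.05),
        },
        seed=42,
    )
    session, gt = synth.generate_session(cfg)
    return cfg, session, gt


@pytest.fixture(scope="session")
def small_tensor(small_session):
    cfg, session, gt = small_session
    z = zscore_traces(session)
    return align_trials(z)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
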