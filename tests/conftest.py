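import numpy as np
import pandas as pd
import pytest

from topotrack.trajectory import MotionConfig, generate_session
from topotrack.synth import SynthConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_session():
    """Ten study-parameter trials, shared across tests (read-only)."""
    return generate_session(MotionConfig(), 10, rng=123)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small simulated study: 10 trials, 2 subjects, clear responses."""
    return simulate_dataset(
        MotionConfig(), SynthConfig(n_subjects=2, snr=2.0), n_trials=10, rng=42
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def pooled_epochs(dataset, erp_module, events=None):
    """Preprocess + epoch every subject and pool into one EpochSet."""
    events = dataset.target_events if events is None else events
    pre = [erp_module.preprocess(r) for r in dataset.recordings]
    eps = [erp_module.epoch(r, events) for r in pre]
    pooled = erp_module.EpochSet(
        np.concatenate([e.data for e in eps]),
        eps[0].times,
        pd.concat([e.info for e in eps], ignore_index=True),
        eps[0].ch_names,
    )
    return pre, pooled
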