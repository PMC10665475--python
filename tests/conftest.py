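import numpy as np
import pytest

import respfusion as rf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """One short simulated recording with exact ground truth (shared)."""
    subj = rf.SimSubject("s01", breathing_rate_bpm=15.0, seed=11)
    return rf.simulate_recording(subj, rf.SCENARIO_PROFILES["city"], duration_s=60.0)


@pytest.fixture(scope="session")
def toy_snippets():
    """Small labeled snippet set with a learnable channel/label relation.

    Positive snippets carry a centered pulse on every channel; negatives are
    pure noise.  Balanced enough to train the tiny CNNs in a few epochs.
    """
    rng = np.random.default_rng(5)
    n, channels, length = 240, 4, 201
    labels = (np.arange(n) % 2).astype(np.int64)
    data = 0.3 * rng.normal(size=(n, channels, length))
    pulse = np.exp(-0.5 * ((np.arange(length) - 100) / 8.0) ** 2)
    data[labels == 1] += pulse[None, None, :]
    return rf.SnippetSet(
        data=data,
        channel_names=rf.MODEL_CHANNEL_ORDER,
        starts=np.arange(n, dtype=np.int64),
        subject_ids=np.full(n, "toy", dtype=object),
        scenarios=np.full(n, "city", dtype=object),
        labels=labels,
    )
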