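import numpy as np
import pytest

from fetalmove import (
    SimConfig,
    feature_matrix,
    label_epochs,
    preprocess_epoch,
    segment,
    simulate_recording,
)


@pytest.fixture(scope="session")
def sim_features():
    """Feature matrix (with labels) from a 200-epoch default-condition run."""
    cfg = SimConfig(duration_s=512.0, seed=7)
    rec = simulate_recording(cfg)
    labels = label_epochs(rec)
    epochs = segment(rec, labels=labels)
    processed = [preprocess_epoch(ep) for ep in epochs]
    return feature_matrix(processed)


@pytest.fixture(scope="session")
def small_recording():
    """A short recording with a balanced-ish class mix for fold-based tests."""
    cfg = SimConfig(duration_s=128.0, burst_rate=12.0, seed=5)
    return simulate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
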