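import numpy as np
import pytest

from popmanifold import preprocess, synthio


@pytest.fixture(scope="session")
def small_session():
    """Small synthetic session with free epoch, shared across tests."""
    cfg = synthio.SimConfig(
        n_neurons=40, n_trials_per_class=12, seed=7, free_duration_s=60.0
    )
    session, truth = synthio.generate_session(cfg)
    return session, truth, cfg


@pytest.fixture(scope="session")
def small_binned(small_session):
    session, truth, cfg = small_session
    binned = preprocess.preprocess_session(session)
    return binned, truth


def state_labels(truth, n_bins=None):
    """Ground-truth latent states as manifold-cluster labels (0 → sentinel)."""
    lab = truth.state_sequence.astype(int).copy()
    lab[lab == 0] = -1
    if n_bins is not None:
        lab = lab[:n_bins]
    return lab
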