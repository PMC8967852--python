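"""Shared fixtures: a small multi-subject synthetic dataset and briefly
trained leave-one-out fold models, reused across the unit-test modules."""

import numpy as np
import pytest

from ictalfeat.preprocess import build_epochset
from ictalfeat.spectral import engineered_feature_table
from ictalfeat.synthetic import SyntheticConfig, generate_dataset
from ictalfeat.train_probe import run_loo


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_subjects=6, channels_per_subject=2, seed=7)


@pytest.fixture(scope="session")
def recordings(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def epochs(recordings):
    return build_epochset(recordings)


@pytest.fixture(scope="session")
def engineered(epochs):
    return engineered_feature_table(epochs.X, epochs.sample_rate)


@pytest.fixture(scope="session")
def fdbb_folds(epochs):
    """Short FDBB leave-one-out training (enough to separate the classes)."""
    return run_loo(epochs, "fdbb", n_val_subjects=2, seed=1,
                   max_epochs=15, patience=5)


@pytest.fixture(scope="session")
def tdbb_folds(epochs):
    """Minimal TDBB fold training — provides real z0..z15 encodings for the
    ensemble plumbing without convolutional training cost."""
    return run_loo(epochs, "tdbb", n_val_subjects=2, seed=1,
                   max_epochs=1, patience=1)


@pytest.fixture(scope="session")
def fold_models(fdbb_folds, tdbb_folds):
    out = {}
    for fr in fdbb_folds:
        out.setdefault(fr.heldout_subject, {})["fdbb"] = fr.model
    for fr in tdbb_folds:
        out.setdefault(fr.heldout_subject, {})["tdbb"] = fr.model
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
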