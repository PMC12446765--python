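"""Shared fixtures: the synthetic one-class dataset and a model trained on it.

Training the study-scale model takes a few minutes on one CPU, so it is a
session fixture shared by the end-to-end and explainability tests.
"""

from __future__ import annotations

import pytest

from smirtd.presets import small_model_config, small_train_config
from smirtd.synthetic import SyntheticSpec, generate
from smirtd.training import train

N_TRAIN = 200
N_HELDOUT = 30
N_NEG = 30
DATA_SEED = 7
TRAIN_SEED = 1


@pytest.fixture(scope="session")
def synthetic_dataset():
    """(training positives, held-out positives, negatives) from the default
    planted-motif spec."""
    spec = SyntheticSpec(n_pos=N_TRAIN + N_HELDOUT, n_neg=N_NEG, seed=DATA_SEED)
    pos, neg = generate(spec)
    return pos[:N_TRAIN], pos[N_TRAIN:], neg


@pytest.fixture(scope="session")
def trained_bundle(synthetic_dataset):
    """Study-scale model trained on the synthetic positives (masking 0.5)."""
    train_pos, _, _ = synthetic_dataset
    tc = small_train_config(masking_ratio=0.5, seed=TRAIN_SEED)
    model, history = train(train_pos, small_model_config(seed=TRAIN_SEED), tc)
    return model, tc, history
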