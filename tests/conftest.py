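"""Shared fixtures: small phantom image sets and a trained scaled-down model.

The trained pipeline fixture is session-scoped because training the
extractor is the most expensive step; every test that needs deep features
shares one trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from fundusnet.model import ModelConfig, TrainConfig, build_model, extract_deep_features, train_model
from fundusnet.synthdata import SynthImageSpec, SynthTableSpec, generate_feature_table, generate_phantom_images

# scaled-down study conditions used throughout the suite: 8 classes x 40
# phantoms at 32 px, a 2-block extractor with a 16-unit LSTM and the full
# 350-wide FC1 (the wide FC1 over a narrow recurrent state is what gives the
# selector redundant columns to prune, as in the full-size architecture)
SMALL_MODEL = dict(
    n_residual_blocks=2,
    block_filters=(12, 16),
    lstm_units=16,
    fc1_width=350,
    n_classes=8,
    input_size=32,
)
SMALL_TRAIN = dict(batch_size=32, learning_rate=0.01, max_epochs=40, seed=0)


@pytest.fixture(scope="session")
def phantom_set():
    spec = SynthImageSpec(n_per_class=40, image_size=32, seed=0)
    return generate_phantom_images(spec)


@pytest.fixture(scope="session")
def trained_pipeline(phantom_set):
    """(images, labels, trained model, history, deep-feature matrix)."""
    imgs, labels = phantom_set
    model = build_model(ModelConfig(**SMALL_MODEL), seed=0)
    model, history = train_model(model, imgs, labels, TrainConfig(**SMALL_TRAIN))
    feats = extract_deep_features(model, imgs).matrix
    return imgs, labels, model, history, feats


@pytest.fixture()
def small_table():
    spec = SynthTableSpec(
        n_samples=200, n_features=10, n_informative=3, n_classes=4, effect_size=4.0, seed=11
    )
    return generate_feature_table(spec)


def random_small_instance(seed: int, n_max: int = 10, p_max: int = 4, n_classes: int = 3):
    """A tiny random labelled dataset for oracle comparisons.

    Guarantees every class has at least two members.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    p = int(rng.integers(1, p_max + 1))
    X = rng.normal(size=(n, p))
    C = min(n_classes, n // 2)
    y = np.concatenate([np.repeat(np.arange(C), 2), rng.integers(0, C, n - 2 * C)])
    rng.shuffle(y)
    return X, y
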