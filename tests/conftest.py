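"""Shared fixtures.

The expensive end-to-end resources (a trained reduced-width network and its
held-out evaluation) are session-scoped and shared between the inference
smoke tests and the acceptance tests, so the network is trained exactly once
per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from cmrseg.augment import AugmentConfig
from cmrseg.evaluate import evaluate_dataset
from cmrseg.inference import segment_study
from cmrseg.phantom import PhantomConfig, generate_domain, generate_study
from cmrseg.preprocess import PreprocessConfig
from cmrseg.train import TrainConfig, train_model
from cmrseg.unet import UNet, UNetConfig

SEED = 12345


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def phantom_study():
    """One clean default phantom subject with truth."""
    return generate_study(PhantomConfig(), seed=SEED)


@pytest.fixture(scope="session")
def desk_scale_setup():
    """The desk-scale study conditions: reduced-width network (8 base
    filters), 96 x 96 crop at 1.25 mm, 40 domain-A training subjects,
    10 held-out domain-A test subjects."""
    return {
        "preprocess": PreprocessConfig(crop_size=(96, 96)),
        "augment": AugmentConfig(),
        "model": UNetConfig(base_filters=8),
        "train": TrainConfig(batch_size=10, initial_lr=0.05, epochs=6, seed=SEED),
        "n_train": 40,
        "n_val": 4,
        "n_test": 10,
    }


@pytest.fixture(scope="session")
def trained_model(desk_scale_setup):
    """Train the desk-scale network once on domain-A phantoms."""
    s = desk_scale_setup
    train_set = [st for st, _ in generate_domain("A", s["n_train"], seed=SEED)]
    val_set = [st for st, _ in generate_domain("A", s["n_val"], seed=SEED + 1)]
    net = UNet(s["model"], seed=s["train"].seed)
    net, history = train_model(net, train_set, val_set, s["train"],
                               s["preprocess"], s["augment"])
    return net, history


@pytest.fixture(scope="session")
def held_out_evaluation(trained_model, desk_scale_setup):
    """Segment the held-out domain-A subjects and score them."""
    net, _ = trained_model
    s = desk_scale_setup
    test_set = [st for st, _ in generate_domain("A", s["n_test"], seed=SEED + 2)]
    preds = {st.subject_id: segment_study(net, st, s["preprocess"])
             for st in test_set}
    report = evaluate_dataset(preds, test_set)
    return report, test_set, preds
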