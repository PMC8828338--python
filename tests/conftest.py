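"""Shared fixtures: small phantoms and the session-scoped end-to-end run."""

from __future__ import annotations

import numpy as np
import pytest

from dbtseg.config import EvaluationGroup, PostprocessGroup
from dbtseg.estimator import DilatedFCNSegmenter
from dbtseg.evaluate import dice_coefficient, froc, roc_auc
from dbtseg.phantom import PhantomSpec, generate_dataset, generate_phantom

E2E_SEED = 42


@pytest.fixture(scope="session")
def small_phantom():
    """One seeded desk-scale phantom volume with two lesions."""
    return generate_phantom(PhantomSpec(n_lesions=2, seed=11))


@pytest.fixture(scope="session")
def phantom_dataset():
    """Four small seeded phantom volumes (cheap, for unit tests)."""
    spec = PhantomSpec(shape=(10, 96, 96), diameter_range_mm=(2.0, 3.5))
    return generate_dataset(4, spec, seed=5, lesion_range=(1, 2))


@pytest.fixture(scope="session")
def e2e_result():
    """The full synthetic-recovery experiment, run once per session.

    Generates 12 desk-scale phantoms (1-3 lesions each), trains the
    default dilated FCN on 9, and evaluates heatmaps and final masks on
    the held-out 3, alongside an untrained baseline.
    """
    data = generate_dataset(12, PhantomSpec(), seed=E2E_SEED, lesion_range=(1, 3))
    train_X = [v for v, _ in data[:9]]
    train_y = [m for _, m in data[:9]]
    test_X = [v for v, _ in data[9:]]
    test_y = [m for _, m in data[9:]]

    est = DilatedFCNSegmenter(random_state=E2E_SEED)
    est.fit(train_X, train_y)
    heatmaps = est.predict_proba(test_X)
    preds = est.predict(test_X)

    dices, aucs = [], []
    for pred, hm, truth in zip(preds, heatmaps, test_y):
        dices.append(dice_coefficient(pred, truth))
        aucs.append(roc_auc(hm, truth))
    curve = froc(heatmaps, test_y, post_cfg=PostprocessGroup(), eval_cfg=EvaluationGroup())

    baseline = DilatedFCNSegmenter(
        random_state=E2E_SEED, epochs=1, batches_per_epoch=1, learning_rate=0.0
    )
    baseline.fit(train_X[:1], train_y[:1])
    base_dices = []
    for pred, truth in zip(baseline.predict(test_X), test_y):
        try:
            base_dices.append(dice_coefficient(pred, truth))
        except ZeroDivisionError:
            base_dices.append(0.0)

    return {
        "estimator": est,
        "test_X": test_X,
        "test_y": test_y,
        "heatmaps": heatmaps,
        "preds": preds,
        "dices": dices,
        "aucs": aucs,
        "froc": curve,
        "baseline_dices": base_dices,
    }
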