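"""Training: soft Dice loss values and identities, fold bookkeeping, the
training loop's reproducibility and cross-validation accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parotidseg import metrics as metrics_mod
from parotidseg.autodiff import Tensor
from parotidseg.data import ROI_NAMES
from parotidseg.errors import ConfigError
from parotidseg.io_preprocess import make_slice_dataset
from parotidseg.model import ModelConfig, build_model
from parotidseg.phantoms import PhantomSpec, generate_cohort
from parotidseg.train import (
    FoldSplit,
    TrainConfig,
    make_folds,
    mean_channel_dice,
    run_cross_validation,
    soft_dice_loss,
    train_fold,
)

TINY_MODEL = dict(in_channels=3, input_size=32, depth=2, base_filters=4,
                  encoder_block_allocation=[1, 1, 1], decoder_blocks_per_level=1)


# -- loss ------------------------------------------------------------------------


def test_loss_zero_for_perfect_binary_prediction():
    t = np.zeros((1, 6, 6, 1))
    t[0, 1:4, 1:4, 0] = 1
    assert soft_dice_loss(t, t, smoothing=0.0) == pytest.approx(0.0, abs=1e-12)


def test_loss_one_for_disjoint_masks():
    a = np.zeros((1, 6, 6, 1))
    b = np.zeros((1, 6, 6, 1))
    a[0, :2, :, 0] = 1
    b[0, 4:, :, 0] = 1
    assert soft_dice_loss(a, b, smoothing=0.0) == pytest.approx(1.0, abs=1e-12)


def test_loss_worked_half_probability_example():
    # uniform 0.5 prediction, 8 of 16 pixels foreground: soft dice = 8/16
    pred = np.full((1, 4, 4, 1), 0.5)
    target = np.zeros((1, 4, 4, 1))
    target[0, :2, :, 0] = 1
    assert target.sum() == 8
    assert soft_dice_loss(pred, target, smoothing=0.0) == pytest.approx(0.5)


def test_loss_matches_metric_dice_for_binary_predictions(rng):
    for _ in range(10):
        p = (rng.random((1, 5, 5, 1)) < 0.4).astype(float)
        t = (rng.random((1, 5, 5, 1)) < 0.4).astype(float)
        if p.sum() + t.sum() == 0:
            continue
        loss = soft_dice_loss(p, t, smoothing=0.0)
        d = metrics_mod.dice(p[0, :, :, 0], t[0, :, :, 0])
        assert abs(loss - (1.0 - d)) < 1e-12
        # symmetry in (p, t) for binary predictions
        assert soft_dice_loss(t, p, smoothing=0.0) == pytest.approx(loss, abs=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_loss_bounded_on_unit_inputs(seed):
    rng = np.random.default_rng(seed)
    p = rng.random((2, 4, 4, 4))
    t = (rng.random((2, 4, 4, 4)) < 0.3).astype(float)
    loss = soft_dice_loss(p, t, smoothing=1.0)
    assert 0.0 <= loss <= 1.0


def test_loss_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        soft_dice_loss(np.zeros((1, 4, 4, 4)), np.zeros((1, 4, 4, 3)))


def test_loss_backward_produces_gradients(rng):
    p = Tensor(rng.random((1, 4, 4, 2)).astype(np.float32), requires_grad=True)
    t = (rng.random((1, 4, 4, 2)) < 0.5).astype(np.float32)
    soft_dice_loss(p, t).backward()
    assert p.grad is not None and np.abs(p.grad).max() > 0


# -- folds ------------------------------------------------------------------------


def test_folds_of_285_patients_have_28_or_29_validation_each():
    ids = [f"p{i:03d}" for i in range(285)]
    folds = make_folds(ids, folds=10, seed=0)
    seen = []
    for f in folds:
        n = len(f.validation_patient_ids)
        assert n in (28, 29)
        assert len(f.train_patient_ids) == 285 - n
        assert not f.train_patient_ids & f.validation_patient_ids
        seen.extend(f.validation_patient_ids)
    assert sorted(seen) == sorted(ids)  # each patient validates exactly once


def test_folds_deterministic_under_seed():
    ids = [f"p{i}" for i in range(25)]
    assert make_folds(ids, 5, seed=3) == make_folds(ids, 5, seed=3)
    assert make_folds(ids, 5, seed=3) != make_folds(ids, 5, seed=4)


def test_ten_ids_ten_folds_are_singletons():
    ids = [f"p{i}" for i in range(10)]
    folds = make_folds(ids, 10, seed=1)
    vals = [f.validation_patient_ids for f in folds]
    assert all(len(v) == 1 for v in vals)
    assert len(set(frozenset(v) for v in vals)) == 10


def test_folds_reject_duplicates_and_small_cohorts():
    with pytest.raises(ValueError):
        make_folds(["a", "a", "b"], 2)
    with pytest.raises(ValueError):
        make_folds(["a", "b"], 3)


def test_train_config_validation():
    with pytest.raises(ConfigError):
        TrainConfig(folds=1)
    with pytest.raises(ConfigError):
        TrainConfig(epochs=0)
    assert TrainConfig(folds=10).validation_fraction == pytest.approx(0.1)


# -- training loop ------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = PhantomSpec(grid_shape=(4, 32, 32), laterality="both", seed=0)
    return generate_cohort(4, spec, seed=5, proportions={"both": 1.0})


@pytest.fixture(scope="module")
def tiny_samples(tiny_cohort):
    return make_slice_dataset(tiny_cohort, None, target_size=32)


def test_zero_learning_rate_leaves_parameters_unchanged(tiny_samples):
    model = build_model(ModelConfig(**TINY_MODEL, seed=0))
    before = [p.data.copy() for p in model.parameters()]
    fold = FoldSplit(0, frozenset(s.patient_id for s in tiny_samples), frozenset())
    train_fold(model, fold, tiny_samples, TrainConfig(learning_rate=0.0, epochs=1))
    for p, b in zip(model.parameters(), before):
        np.testing.assert_array_equal(p.data, b)


def test_history_length_and_loss_decreases(tiny_samples):
    model = build_model(ModelConfig(**TINY_MODEL, seed=0))
    fold = FoldSplit(0, frozenset(s.patient_id for s in tiny_samples), frozenset())
    cfg = TrainConfig(learning_rate=1e-2, epochs=6, batch_size=4, seed=1)
    _, history = train_fold(model, fold, tiny_samples, cfg)
    assert len(history) == 6
    assert history[-1]["train_loss"] < history[0]["train_loss"]


def test_empty_training_set_rejected(tiny_samples):
    model = build_model(ModelConfig(**TINY_MODEL, seed=0))
    fold = FoldSplit(0, frozenset(), frozenset(s.patient_id for s in tiny_samples))
    with pytest.raises(ValueError):
        train_fold(model, fold, tiny_samples, TrainConfig(epochs=1))


def test_training_reproducible_with_augmentation(tiny_samples):
    from parotidseg.augment import AugmentConfig

    results = []
    for _ in range(2):
        model = build_model(ModelConfig(**TINY_MODEL, seed=2))
        fold = FoldSplit(0, frozenset(s.patient_id for s in tiny_samples),
                         frozenset())
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=4, seed=9)
        _, history = train_fold(model, fold, tiny_samples, cfg, AugmentConfig())
        results.append((history, [p.data.copy() for p in model.parameters()]))
    assert results[0][0] == results[1][0]
    for a, b in zip(results[0][1], results[1][1]):
        np.testing.assert_array_equal(a, b)


def test_cross_validation_bookkeeping(tiny_cohort):
    model_cfg = ModelConfig(**TINY_MODEL, seed=0)
    train_cfg = TrainConfig(learning_rate=1e-3, epochs=1, batch_size=4,
                            folds=2, seed=0)
    report, details = run_cross_validation(tiny_cohort, model_cfg, train_cfg,
                                           return_details=True)
    # every patient evaluated exactly once, by the fold that held it out
    assert len(report.per_case) == len(tiny_cohort) * len(ROI_NAMES)
    evaluated = set(report.per_case["patient_id"])
    assert evaluated == {c.patient_id for c in tiny_cohort}
    held_out = set()
    for fold in details["folds"]:
        held_out |= fold.validation_patient_ids
    assert held_out == evaluated
    assert {"dice_mean", "hd95_mm_mean"} <= set(report.summary.columns)


def test_mean_channel_dice_perfect_for_labels_as_predictions(tiny_samples):
    class Oracle:
        def eval(self):
            return self

        def __call__(self, batch):
            # emit the ground-truth labels of the batch: requires samples in
            # the same order they were stacked
            return Tensor(self._labels)

    oracle = Oracle()
    oracle._labels = np.stack([s.label for s in tiny_samples[:4]]).astype(np.float32)
    out = mean_channel_dice(oracle, tiny_samples[:4], batch_size=4)
    assert out["mean"] == pytest.approx(1.0)
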