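"""Soft-Dice training, patient-level k-fold splitting and cross-validation.

The loss is 1 minus the soft Dice coefficient, one Dice per output channel
averaged uniformly over the four channels:

    soft_dice_c = (2 * sum(p * t) + s) / (sum(p) + sum(t) + s)

with a smoothing constant s (default 1.0) so background-only channels are
well-defined and the loss stays differentiable. By default the sums pool all
batch items (see ``soft_dice_loss`` for the per-sample alternative). The optimizer is RMSprop at
learning rate 1e-4 for 200 epochs by default. Cross-validation splits at the
patient level: all slices of a patient fall on one side of each fold, every
patient is validated exactly once, and fold sizes differ by at most one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import metrics as metrics_mod
from .autodiff import Tensor, no_grad
from .data import ROI_NAMES, SliceSample
from .errors import ConfigError
from .layers import RMSprop
from .model import AttentionUNet, ModelConfig, build_model, predict_case


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    optimizer: str = "rmsprop"
    epochs: int = 200
    batch_size: int = 8
    loss_smoothing: float = 1.0
    loss_reduction: str = "batch"
    folds: int = 10
    seed: int = 0
    threshold: float = 0.5
    select_best: bool = False  # keep best-validation checkpoint (off = final epoch)

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.folds < 2:
            raise ConfigError(
                "folds must be >= 2 (validation fraction 1/folds is undefined otherwise)"
            )
        if self.optimizer.lower() != "rmsprop":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")

    @property
    def validation_fraction(self) -> float:
        return 1.0 / self.folds


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_patient_ids: frozenset[str]
    validation_patient_ids: frozenset[str]


def soft_dice_loss(predictions, targets, smoothing: float = 1.0,
                   reduction: str = "batch"):
    """1 - mean soft Dice; works on autodiff Tensors and plain arrays.

    The first axis is the batch, the last the channel. With
    ``reduction='batch'`` (default) the intersection and volume sums are
    pooled over the whole batch before forming one Dice per channel; with
    ``'per_sample'`` each (sample, channel) pair gets its own smoothed Dice
    and the mean is taken over both. The pooled form is the default because
    background-only slices otherwise reward an all-empty prediction through
    the smoothing term, which can silence the small tumor channels entirely.
    """
    pred_dtype = (predictions.data if isinstance(predictions, Tensor)
                  else np.asarray(predictions)).dtype
    target = np.asarray(targets, dtype=np.result_type(pred_dtype, np.float32))
    shape = predictions.shape
    if tuple(shape) != target.shape:
        raise ValueError(f"shape mismatch: predictions {tuple(shape)} vs targets {target.shape}")
    nd = len(shape)
    if reduction == "batch":
        axes = tuple(range(nd - 1)) if nd >= 3 else None
    elif reduction == "per_sample":
        axes = tuple(range(1, nd - 1)) if nd >= 3 else None
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    inter = (predictions * target).sum(axis=axes)
    psum = predictions.sum(axis=axes)
    tsum = target.sum(axis=axes)
    dice = (2.0 * inter + smoothing) / (psum + tsum + smoothing)
    return 1.0 - dice.mean()


def make_folds(patient_ids, folds: int = 10, seed: int = 0) -> list[FoldSplit]:
    """Random patient-level partition into near-equal folds (sizes differ <= 1)."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if len(ids) < folds:
        raise ValueError(f"need at least {folds} patients for {folds} folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    chunks = np.array_split(np.arange(len(order)), folds)
    splits = []
    for k, chunk in enumerate(chunks):
        val = frozenset(order[i] for i in chunk)
        splits.append(
            FoldSplit(
                fold_index=k,
                train_patient_ids=frozenset(ids) - val,
                validation_patient_ids=val,
            )
        )
    return splits


def _batches(n: int, batch_size: int):
    for start in range(0, n, batch_size):
        yield range(start, min(start + batch_size, n))


def mean_channel_dice(model: AttentionUNet, samples: list[SliceSample],
                      threshold: float = 0.5, batch_size: int = 8) -> dict[str, float]:
    """Binary Dice per ROI channel over the stacked slices, plus the mean.

    Predictions of all slices are concatenated into one stack per channel and
    compared against the stacked labels with the exact voxel-count Dice.
    """
    model.eval()
    preds, labels = [], []
    with no_grad():
        for idx in _batches(len(samples), batch_size):
            chunk = [samples[i] for i in idx]
            batch = np.stack([s.image for s in chunk]).astype(np.float32)
            preds.append(model(batch).data >= threshold)
            labels.append(np.stack([s.label for s in chunk]))
    pred = np.concatenate(preds)
    label = np.concatenate(labels)
    out = {
        roi: metrics_mod.dice(label[..., i], pred[..., i])
        for i, roi in enumerate(ROI_NAMES)
    }
    out["mean"] = float(np.mean([out[r] for r in ROI_NAMES]))
    return out


def train_fold(model: AttentionUNet, fold: FoldSplit, samples: list[SliceSample],
               train_config: TrainConfig, augment_config=None):
    """Train one model on the fold's training patients.

    Returns (model, history); history holds one dict per epoch with the mean
    training loss and, when the fold has validation patients, the mean binary
    validation Dice. Fully reproducible: the data order and the augmentation
    stream derive from train_config.seed + fold_index.
    """
    train_samples = [s for s in samples if s.patient_id in fold.train_patient_ids]
    val_samples = [s for s in samples if s.patient_id in fold.validation_patient_ids]
    if not train_samples:
        raise ValueError(f"fold {fold.fold_index}: empty training set")
    rng = np.random.default_rng(int(train_config.seed) + int(fold.fold_index))
    optimizer = RMSprop(model.parameters(), lr=train_config.learning_rate)
    history: list[dict] = []
    best = (-np.inf, None)
    for epoch in range(train_config.epochs):
        model.train()
        order = rng.permutation(len(train_samples))
        losses = []
        for idx in _batches(len(order), train_config.batch_size):
            chunk = [train_samples[order[i]] for i in idx]
            images, labels = [], []
            for s in chunk:
                image, label = s.image, s.label
                if augment_config is not None:
                    from .augment import augment_sample

                    image, label = augment_sample(image, label, rng, augment_config)
                images.append(image)
                labels.append(label)
            x = Tensor(np.stack(images).astype(np.float32))
            y = np.stack(labels).astype(np.float32)
            loss = soft_dice_loss(model(x), y, train_config.loss_smoothing,
                                  train_config.loss_reduction)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_samples:
            val = mean_channel_dice(model, val_samples, train_config.threshold,
                                    train_config.batch_size)
            record["val_dice"] = val["mean"]
            if train_config.select_best and val["mean"] > best[0]:
                best = (val["mean"], [a.copy() for a in model.state_arrays()])
        history.append(record)
    if train_config.select_best and best[1] is not None:
        model.load_state_arrays(best[1])
    return model, history


def run_cross_validation(cases, model_config: ModelConfig,
                         train_config: TrainConfig, augment_config=None,
                         sequences=None, return_details: bool = False):
    """Patient-level k-fold cross-validation on a cohort.

    Trains one model per fold and evaluates every patient with the model that
    held it out; per-case metrics are aggregated into a CohortReport.
    """
    from .io_preprocess import make_slice_dataset

    cases = list(cases)
    if not cases:
        raise ValueError("empty cohort")
    ids = [c.volume.patient_id if hasattr(c, "volume") else c[0].patient_id
           for c in cases]
    by_id = dict(zip(ids, cases))
    folds = make_folds(ids, train_config.folds, train_config.seed)
    samples = make_slice_dataset(cases, sequences,
                                 target_size=model_config.input_size)
    case_metrics, histories, models = [], [], []
    for fold in folds:
        cfg = dataclasses.replace(
            model_config, seed=int(model_config.seed) + int(fold.fold_index)
        )
        model = build_model(cfg)
        model, history = train_fold(model, fold, samples, train_config,
                                    augment_config)
        histories.append(history)
        if return_details:
            models.append(model)
        for pid in sorted(fold.validation_patient_ids):
            case = by_id[pid]
            labels = case.labels if hasattr(case, "labels") else case[1]
            pred = predict_case(model, case, threshold=train_config.threshold,
                                sequences=sequences)
            case_metrics.append(metrics_mod.evaluate_case(pid, labels, pred))
    report = metrics_mod.aggregate(case_metrics)
    if return_details:
        return report, {"histories": histories, "models": models, "folds": folds}
    return report
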