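"""Training regimen and trial-stratified 6-fold cross-validation.

Trials — not windows — are the unit of fold membership: each fold
receives one trial per (participant, surface) pair when six trials exist,
so no trial's windows ever straddle the train/validation/test boundary.
For test fold k the validation fold is (k mod 6) + 1 and the remaining
four folds train; the min-max scaler is fitted on each rotation's
training segments only.  Training uses Adam (lr 0.001), batch size 32,
sparse categorical cross-entropy, early stopping on validation accuracy
(patience 25, best-weights restore) and learning-rate reduction on
plateau (patience 10, factor 0.1, floor 1e-6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GaitDataset, SegmentSet, Site, Surface, TrialKey
from .fusion import assemble_segments
from .model import ModelHandle, build_surface_cnn
from .nn import Adam
from .preprocess import apply_scaler, fit_scaler

__all__ = [
    "LeakageError",
    "TrainConfig",
    "FoldPlan",
    "make_fold_plan",
    "TrainingHistory",
    "train_one_fold",
    "CVResult",
    "cross_validate",
]


class LeakageError(RuntimeError):
    """Train/validation/test sets share a trial."""


@dataclass
class TrainConfig:
    """Hyper-parameters of one training run."""

    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 32
    patience_stop: int = 25
    patience_lr: int = 10
    lr_factor: float = 0.1
    lr_min: float = 1e-6
    monitor: str = "accuracy"  # or "loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience_lr >= self.patience_stop:
            raise ValueError("patience_lr must be < patience_stop")
        if self.monitor not in ("accuracy", "loss"):
            raise ValueError("monitor must be 'accuracy' or 'loss'")


@dataclass
class FoldPlan:
    """Assignment of each trial to one of n_folds folds.

    ``assignment`` maps (participant, surface) to {trial_index: fold};
    folds are numbered 1..n_folds.  Pairs with exactly n_folds trials give
    one trial to every fold; pairs with fewer are spread round-robin over
    a seed-shuffled fold order.
    """

    assignment: dict[tuple[int, Surface], dict[int, int]]
    n_folds: int = 6

    def fold_of(self, key: TrialKey) -> int:
        pid, surface, idx = key
        return self.assignment[(pid, surface)][idx]

    def trials_in_fold(self, fold: int) -> set[TrialKey]:
        out = set()
        for (pid, surface), mapping in self.assignment.items():
            for idx, f in mapping.items():
                if f == fold:
                    out.add((pid, surface, idx))
        return out


def make_fold_plan(dataset: GaitDataset, seed: int = 0,
                   n_folds: int = 6) -> FoldPlan:
    """Stratify trials over folds, one per (participant, surface) pair."""
    if len(dataset) == 0:
        raise ValueError("cannot plan folds for an empty dataset")
    rng = np.random.default_rng(seed)
    pairs: dict[tuple[int, Surface], list[int]] = {}
    for key in sorted(dataset.keys):
        pid, surface, idx = key
        pairs.setdefault((pid, surface), []).append(idx)
    assignment: dict[tuple[int, Surface], dict[int, int]] = {}
    for pair in sorted(pairs):
        indices = sorted(pairs[pair])
        fold_order = rng.permutation(n_folds) + 1
        assignment[pair] = {
            idx: int(fold_order[i % n_folds]) for i, idx in enumerate(indices)
        }
    return FoldPlan(assignment=assignment, n_folds=n_folds)


@dataclass
class TrainingHistory:
    """Per-epoch traces of one training run."""

    loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_epoch: int = 0


def _val_metrics(handle: ModelHandle, X: np.ndarray, y: np.ndarray
                 ) -> tuple[float, float]:
    proba = handle.network.predict_proba(X)
    pred = proba.argmax(axis=1)
    acc = float((pred == y).mean())
    eps = 1e-12
    loss = float(-np.log(proba[np.arange(len(y)), y] + eps).mean())
    return acc, loss


def train_one_fold(
    train_set: SegmentSet,
    val_set: SegmentSet,
    handle: ModelHandle,
    config: TrainConfig,
) -> tuple[ModelHandle, TrainingHistory]:
    """Train with early stopping and LR-on-plateau; restore best weights.

    "No improvement" means not strictly better than the best monitored
    value so far (min-delta 0).  Raises :class:`LeakageError` if train and
    validation share any source trial.
    """
    overlap = train_set.source_trials & val_set.source_trials
    if overlap:
        raise LeakageError(f"train/val share trials: {sorted(overlap)[:3]} ...")
    rng = np.random.default_rng(config.seed)
    opt = Adam(lr=config.learning_rate)
    history = TrainingHistory()
    best_metric = -np.inf
    best_weights = handle.network.get_weights()
    since_best = 0
    since_lr = 0
    Xtr = np.ascontiguousarray(train_set.X, dtype=np.float32)
    ytr = train_set.y
    Xva = np.ascontiguousarray(val_set.X, dtype=np.float32)
    yva = val_set.y
    n = Xtr.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            losses.append(handle.network.train_batch(Xtr[idx], ytr[idx], opt))
        val_acc, val_loss = _val_metrics(handle, Xva, yva)
        history.loss.append(float(np.mean(losses)))
        history.val_accuracy.append(val_acc)
        history.val_loss.append(val_loss)
        history.learning_rate.append(opt.lr)
        metric = val_acc if config.monitor == "accuracy" else -val_loss
        if metric > best_metric:
            best_metric = metric
            best_weights = handle.network.get_weights()
            history.best_epoch = epoch
            since_best = 0
            since_lr = 0
        else:
            since_best += 1
            since_lr += 1
        if since_lr >= config.patience_lr and opt.lr > config.lr_min:
            opt.lr = max(opt.lr * config.lr_factor, config.lr_min)
            since_lr = 0
        if since_best >= config.patience_stop:
            break
    history.stopped_epoch = epoch
    handle.network.set_weights(best_weights)
    return handle, history


def _single_rotation(
    dataset: GaitDataset,
    groups: list[str],
    sensors: list[Site],
    window_length: int,
    config: TrainConfig,
    plan: FoldPlan,
    test_fold: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """One train/val/test rotation; returns (y_true, y_pred) on the test fold."""
    segments = assemble_segments(dataset, groups, sensors, window_length)
    fold_ids = np.array([plan.fold_of(src) for src in segments.sources])
    val_fold = (test_fold % plan.n_folds) + 1
    test_mask = fold_ids == test_fold
    val_mask = fold_ids == val_fold
    train_mask = ~(test_mask | val_mask)
    if not (test_mask.any() and val_mask.any() and train_mask.any()):
        raise ValueError("empty split in single-rotation evaluation")
    train_set = segments.subset(train_mask)
    scaler = fit_scaler(train_set)
    train_s = apply_scaler(scaler, train_set)
    val_s = apply_scaler(scaler, segments.subset(val_mask))
    test_s = apply_scaler(scaler, segments.subset(test_mask))
    handle = build_surface_cnn(window_length, len(segments.channel_layout),
                               seed=config.seed + test_fold)
    handle, _history = train_one_fold(train_s, val_s, handle, config)
    pred = handle.network.predict(np.ascontiguousarray(test_s.X))
    return test_s.y, pred


@dataclass
class CVResult:
    """Aggregated predictions over the six test-fold rotations."""

    y_true: np.ndarray
    y_pred: np.ndarray
    sources: list[TrialKey]
    histories: list[TrainingHistory]
    fold_plan: FoldPlan
    skipped_folds: list[int] = field(default_factory=list)


def cross_validate(
    dataset: GaitDataset,
    groups: list[str],
    sensors: list[Site],
    window_length: int,
    train_config: TrainConfig | None = None,
    n_folds: int = 6,
    pool_mode: str = "ceil",
    fold_plan: FoldPlan | None = None,
) -> CVResult:
    """Trial-stratified k-fold cross-validation of the surface classifier.

    For each rotation the scaler and the network are fitted from scratch on
    the four training folds, the validation fold drives early stopping, and
    predictions on the test fold are collected; the six rotations'
    predictions are concatenated.
    """
    config = train_config or TrainConfig()
    plan = fold_plan or make_fold_plan(dataset, seed=config.seed,
                                       n_folds=n_folds)
    segments = assemble_segments(dataset, groups, sensors, window_length)
    fold_ids = np.array([plan.fold_of(src) for src in segments.sources])

    y_true_parts, y_pred_parts, sources_all = [], [], []
    histories: list[TrainingHistory] = []
    skipped: list[int] = []
    for k in range(1, plan.n_folds + 1):
        val_fold = (k % plan.n_folds) + 1
        test_mask = fold_ids == k
        val_mask = fold_ids == val_fold
        train_mask = ~(test_mask | val_mask)
        if not test_mask.any() or not train_mask.any() or not val_mask.any():
            warnings.warn(f"fold {k}: empty split after drops; skipped")
            skipped.append(k)
            continue
        train_set = segments.subset(train_mask)
        val_set = segments.subset(val_mask)
        test_set = segments.subset(test_mask)
        scaler = fit_scaler(train_set)
        train_s = apply_scaler(scaler, train_set)
        val_s = apply_scaler(scaler, val_set)
        test_s = apply_scaler(scaler, test_set)
        handle = build_surface_cnn(
            window_length, len(segments.channel_layout),
            pool_mode=pool_mode, seed=config.seed + k)
        handle, history = train_one_fold(train_s, val_s, handle, config)
        histories.append(history)
        pred = handle.network.predict(np.ascontiguousarray(test_s.X))
        y_true_parts.append(test_s.y)
        y_pred_parts.append(pred)
        sources_all.extend(test_s.sources)
    if not y_true_parts:
        raise ValueError("every fold was skipped; nothing evaluated")
    return CVResult(
        y_true=np.concatenate(y_true_parts),
        y_pred=np.concatenate(y_pred_parts),
        sources=sources_all,
        histories=histories,
        fold_plan=plan,
        skipped_folds=skipped,
    )
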