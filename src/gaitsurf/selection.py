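"""Greedy wrapper experiments: signal-group selection, sensor placement,
window-length sweep.

All three harnesses score candidate configurations with an injectable
``evaluator(groups, sensors, window_length) -> ExperimentRecord`` — in
production a cross-validation run of the CNN followed by weighted metrics
(:func:`make_cv_evaluator`), in tests a mock accuracy table.  Accuracy
comparisons use full floating precision; an exact tie rejects the larger
configuration.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import SIGNAL_GROUP_ORDER, GaitDataset, Site
from .metrics import evaluate_predictions
from .training import FoldPlan, TrainConfig, cross_validate, make_fold_plan

__all__ = [
    "ExperimentRecord",
    "SelectionRound",
    "SelectionTrace",
    "Evaluator",
    "make_cv_evaluator",
    "greedy_signal_selection",
    "greedy_sensor_selection",
    "window_sweep",
    "single_factor_grid",
    "DEFAULT_WINDOW_LENGTHS",
    "write_records_csv",
]

DEFAULT_WINDOW_LENGTHS = (100, 200, 300, 400, 500)


@dataclass
class ExperimentRecord:
    """One evaluated configuration with its aggregated weighted metrics."""

    groups: tuple[str, ...]
    sensors: tuple[Site, ...]
    window_length: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    meta: dict = field(default_factory=dict)


Evaluator = Callable[[Sequence[str], Sequence[Site], int], ExperimentRecord]


def make_cv_evaluator(
    dataset: GaitDataset,
    train_config: TrainConfig | None = None,
    fold_plan: FoldPlan | None = None,
    n_folds: int = 6,
) -> Evaluator:
    """Evaluator running cross-validation + weighted metrics.

    One fold plan and seed are shared across every candidate so that
    candidates differ only in configuration.
    """
    config = train_config or TrainConfig()
    plan = fold_plan or make_fold_plan(dataset, seed=config.seed,
                                       n_folds=n_folds)

    def evaluate(groups: Sequence[str], sensors: Sequence[Site],
                 window_length: int) -> ExperimentRecord:
        result = cross_validate(dataset, list(groups), list(sensors),
                                window_length, train_config=config,
                                fold_plan=plan)
        report = evaluate_predictions(result.y_true, result.y_pred)
        return ExperimentRecord(
            groups=tuple(groups),
            sensors=tuple(Site(s) for s in sensors),
            window_length=window_length,
            precision=report.weighted_precision,
            recall=report.weighted_recall,
            f1=report.weighted_f1,
            accuracy=report.accuracy,
            meta={"seed": config.seed,
                  "n_segments": int(len(result.y_true))},
        )

    return evaluate


def make_holdout_evaluator(
    dataset: GaitDataset,
    train_config: TrainConfig | None = None,
    fold_plan: FoldPlan | None = None,
    n_folds: int = 6,
) -> Evaluator:
    """Cheap evaluator: one train/validation/test rotation instead of six.

    Uses the same trial-stratified fold plan as the full evaluator but
    trains a single model per candidate (test fold 1, validation fold 2),
    trading accuracy resolution for a six-fold cost reduction — enough for
    screening rounds where candidates differ grossly.
    """
    from .training import _single_rotation  # local import to avoid cycle

    config = train_config or TrainConfig()
    plan = fold_plan or make_fold_plan(dataset, seed=config.seed,
                                       n_folds=n_folds)

    def evaluate(groups: Sequence[str], sensors: Sequence[Site],
                 window_length: int) -> ExperimentRecord:
        y_true, y_pred = _single_rotation(dataset, list(groups), list(sensors),
                                          window_length, config, plan)
        report = evaluate_predictions(y_true, y_pred)
        return ExperimentRecord(
            groups=tuple(groups),
            sensors=tuple(Site(s) for s in sensors),
            window_length=window_length,
            precision=report.weighted_precision,
            recall=report.weighted_recall,
            f1=report.weighted_f1,
            accuracy=report.accuracy,
            meta={"seed": config.seed, "holdout": True,
                  "n_segments": int(len(y_true))},
        )

    return evaluate


@dataclass
class SelectionRound:
    """One round of a greedy search: the candidates scored and the verdict."""

    candidates: list[tuple]
    accuracies: list[float]
    accepted: tuple | None  # the accepted candidate, or None if stopped


@dataclass
class SelectionTrace:
    rounds: list[SelectionRound] = field(default_factory=list)

    @property
    def n_evaluations(self) -> int:
        return sum(len(r.candidates) for r in self.rounds)

    @property
    def accepted_accuracies(self) -> list[float]:
        out = []
        for r in self.rounds:
            if r.accepted is not None:
                out.append(r.accuracies[r.candidates.index(r.accepted)])
        return out

    def assert_strictly_increasing(self) -> None:
        accs = self.accepted_accuracies
        if any(b <= a for a, b in zip(accs, accs[1:])):
            raise AssertionError(
                f"accepted-path accuracies not strictly increasing: {accs}")


def _score(evaluator: Evaluator, groups, sensors, L,
           records: list[ExperimentRecord]) -> float | None:
    try:
        rec = evaluator(groups, sensors, L)
    except Exception as exc:  # a failed candidate is recorded and skipped
        warnings.warn(f"candidate {groups}/{sensors}/L={L} failed: {exc}")
        return None
    records.append(rec)
    return rec.accuracy


def greedy_signal_selection(
    sensors: Sequence[Site],
    window_length: int,
    evaluator: Evaluator,
    groups: Sequence[str] = SIGNAL_GROUP_ORDER,
) -> tuple[tuple[str, ...], SelectionTrace, list[ExperimentRecord]]:
    """Sequential forward selection over signal groups.

    Round 1 scores every group singly; each later round scores the current
    set extended by each remaining group and accepts the best strictly
    improving candidate, stopping when none improves.
    """
    records: list[ExperimentRecord] = []
    trace = SelectionTrace()
    remaining = list(groups)
    selected: tuple[str, ...] = ()
    best_acc = -np.inf
    while remaining:
        candidates = [selected + (g,) for g in remaining]
        accs = []
        for cand in candidates:
            acc = _score(evaluator, cand, sensors, window_length, records)
            accs.append(-np.inf if acc is None else acc)
        order = int(np.argmax(accs))
        if accs[order] > best_acc:
            accepted = candidates[order]
            trace.rounds.append(SelectionRound(candidates, accs, accepted))
            selected = accepted
            best_acc = accs[order]
            remaining.remove(accepted[-1])
        else:
            trace.rounds.append(SelectionRound(candidates, accs, None))
            break
    trace.assert_strictly_increasing()
    return selected, trace, records


def greedy_sensor_selection(
    groups: Sequence[str],
    window_length: int,
    evaluator: Evaluator,
    sensors: Sequence[Site] = tuple(Site),
) -> tuple[tuple[Site, ...], SelectionTrace, list[ExperimentRecord]]:
    """Rank-and-add sensor placement search.

    Scores each sensor singly, ranks them by accuracy (ties broken by
    canonical site rank), then walks the ranked list adding one sensor at
    a time and keeping it only on strict improvement.  If any sensor was
    rejected along the way, one closing configuration with every sensor is
    also evaluated (kept only if strictly better).
    """
    records: list[ExperimentRecord] = []
    trace = SelectionTrace()
    sensors = [Site(s) for s in sensors]

    singles = [(s,) for s in sensors]
    accs = []
    for cand in singles:
        acc = _score(evaluator, groups, cand, window_length, records)
        accs.append(-np.inf if acc is None else acc)
    ranked = sorted(range(len(sensors)),
                    key=lambda i: (-accs[i], sensors[i].value))
    best_idx = ranked[0]
    selected: tuple[Site, ...] = (sensors[best_idx],)
    best_acc = accs[best_idx]
    trace.rounds.append(SelectionRound(singles, accs, singles[best_idx]))

    rejected = False
    for i in ranked[1:]:
        cand = selected + (sensors[i],)
        acc = _score(evaluator, groups, cand, window_length, records)
        score = -np.inf if acc is None else acc
        if score > best_acc:
            trace.rounds.append(SelectionRound([cand], [score], cand))
            selected = cand
            best_acc = score
        else:
            trace.rounds.append(SelectionRound([cand], [score], None))
            rejected = True

    if rejected and set(selected) != set(sensors):
        full = tuple(sorted(sensors, key=lambda s: s.value))
        acc = _score(evaluator, groups, full, window_length, records)
        score = -np.inf if acc is None else acc
        if score > best_acc:
            trace.rounds.append(SelectionRound([full], [score], full))
            selected = full
            best_acc = score
        else:
            trace.rounds.append(SelectionRound([full], [score], None))
    trace.assert_strictly_increasing()
    return selected, trace, records


def window_sweep(
    groups: Sequence[str],
    sensors: Sequence[Site],
    evaluator: Evaluator,
    lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
) -> list[ExperimentRecord]:
    """Evaluate one configuration per window length."""
    records: list[ExperimentRecord] = []
    for L in lengths:
        acc = _score(evaluator, groups, sensors, L, records)
        if acc is None:
            continue
    return records


def single_factor_grid(
    groups: Sequence[str] = SIGNAL_GROUP_ORDER,
    sensors: Sequence[Site] = tuple(Site),
    lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
) -> list[tuple[str, Site, int]]:
    """All single-group x single-sensor x single-length configurations."""
    return [(g, Site(s), int(L)) for g in groups for s in sensors
            for L in lengths]


def write_records_csv(records: Sequence[ExperimentRecord], path) -> None:
    """Report table: one row per configuration, metrics to three decimals."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Signal Group(s)", "Sensor Location(s)", "L",
                         "PR", "RE", "F1", "ACC"])
        for rec in records:
            writer.writerow([
                ", ".join(rec.groups),
                ", ".join(s.name for s in rec.sensors),
                rec.window_length,
                f"{rec.precision:.3f}",
                f"{rec.recall:.3f}",
                f"{rec.f1:.3f}",
                f"{rec.accuracy:.3f}",
            ])
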