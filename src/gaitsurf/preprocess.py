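"""Signal conditioning: smoothing, missing-value repair, windowing, scaling.

The chain runs in the order smoothing -> cleaning -> (combination) ->
segmentation -> standardization.  Smoothing is a second-order low-pass
Butterworth filter with a 6 Hz cut-off, applied zero-phase
(forward-backward) by default, the biomechanics convention that preserves
gait-event timing.  Missing samples take the nearest preceding value, or
the first subsequent value for leading runs.  Segmentation cuts
non-overlapping windows from sample 0, discarding the remainder.  The
min-max scaler maps each channel to [0, 1] using statistics from the
training fold only; out-of-range validation/test values are not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .core import GaitDataset, SegmentSet, Site, Trial, TrialKey

__all__ = [
    "TooShortTrialError",
    "UnrepairableChannelError",
    "NotFittedError",
    "butterworth_lowpass",
    "fill_missing",
    "drop_unusable",
    "filter_dataset",
    "segment_matrix",
    "segment_trial",
    "ScalerState",
    "fit_scaler",
    "apply_scaler",
]


class TooShortTrialError(ValueError):
    """Series too short for the filter warm-up."""


class UnrepairableChannelError(ValueError):
    """A channel has no observed values to fill from."""


class NotFittedError(RuntimeError):
    """Scaler applied before fitting."""


def butterworth_lowpass(
    series: np.ndarray,
    sample_rate: float = 100.0,
    cutoff_hz: float = 6.0,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth smoothing, per channel.

    Zero-phase (forward-backward) application by default; set
    ``zero_phase=False`` for a causal single pass.  NaN samples are left in
    place: each maximal finite run is filtered independently, and runs
    shorter than the warm-up are passed through unchanged.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    min_len = 3 * order + 1
    if n < min_len:
        raise TooShortTrialError(
            f"series of length {n} shorter than filter warm-up ({min_len})")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sample_rate,
                        output="sos")

    def _apply(block: np.ndarray) -> np.ndarray:
        if zero_phase:
            return signal.sosfiltfilt(sos, block, axis=0)
        return signal.sosfilt(sos, block, axis=0)

    out = x.copy()
    if np.isfinite(x).all():
        out = _apply(x)
    else:
        for c in range(x.shape[1]):
            col = x[:, c]
            finite = np.isfinite(col)
            if finite.all():
                out[:, c] = _apply(col[:, None])[:, 0]
                continue
            # filter each maximal finite run independently
            idx = np.flatnonzero(np.diff(np.concatenate(
                ([0], finite.view(np.int8), [0]))))
            for start, stop in zip(idx[::2], idx[1::2]):
                if stop - start >= min_len:
                    out[start:stop, c] = _apply(col[start:stop, None])[:, 0]
    return out[:, 0] if squeeze else out


def fill_missing(series: np.ndarray) -> np.ndarray:
    """Repair NaN samples: forward-fill, then back-fill leading runs.

    Raises :class:`UnrepairableChannelError` if any channel is entirely
    missing (that trial should go to :func:`drop_unusable` instead).
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    all_nan = np.isnan(x).all(axis=0)
    if all_nan.any():
        raise UnrepairableChannelError(
            f"channel(s) {np.flatnonzero(all_nan).tolist()} entirely missing")
    out = pd.DataFrame(x).ffill().bfill().to_numpy()
    return out[:, 0] if squeeze else out


def drop_unusable(
    dataset: GaitDataset, required_sensors: list[Site]
) -> tuple[GaitDataset, list[TrialKey]]:
    """Exclude trials whose required sensors are absent or fully missing."""
    required = [Site(s) for s in required_sensors]
    kept, dropped = [], []
    for trial in dataset:
        if any(trial.sensor_missing(s) for s in required):
            dropped.append(trial.key)
        else:
            kept.append(trial)
    return GaitDataset(trials=kept, provenance=dataset.provenance), dropped


def filter_dataset(
    dataset: GaitDataset,
    cutoff_hz: float = 6.0,
    order: int = 2,
    zero_phase: bool = True,
) -> GaitDataset:
    """Apply the Butterworth smoother to every present sensor recording.

    Fully missing recordings are passed through untouched (they are the
    business of :func:`drop_unusable`).
    """
    new_trials = []
    for trial in dataset:
        data = {}
        for site, m in trial.data.items():
            if np.isnan(m).all():
                data[site] = m
            else:
                data[site] = butterworth_lowpass(
                    m, sample_rate=trial.sample_rate, cutoff_hz=cutoff_hz,
                    order=order, zero_phase=zero_phase)
        new_trials.append(replace(trial, data=data))
    return GaitDataset(trials=new_trials, provenance=dataset.provenance)


def segment_matrix(x: np.ndarray, window_length: int) -> np.ndarray:
    """Cut [n, C] into floor(n/L) non-overlapping [L, C] windows from 0."""
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    n = x.shape[0]
    k = n // window_length
    return x[: k * window_length].reshape(k, window_length, *x.shape[1:])


def segment_trial(trial: Trial, window_length: int,
                  sensors: list[Site] | None = None) -> list[np.ndarray]:
    """Windows of the trial's stacked sensor matrix (present sensors only)."""
    sites = sensors if sensors is not None else sorted(trial.data)
    mats = [trial.data[Site(s)] for s in sites]
    stacked = np.concatenate(mats, axis=1) if mats else np.empty((trial.n_samples, 0))
    return list(segment_matrix(stacked, window_length))


@dataclass
class ScalerState:
    """Per-channel min-max statistics learned from training segments."""

    mins: np.ndarray
    maxs: np.ndarray
    channel_layout: list
    fitted_from: set[TrialKey]

    def __post_init__(self) -> None:
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in scaler state")


def fit_scaler(training: SegmentSet) -> ScalerState:
    """Learn per-channel global min/max over all training segments."""
    flat = training.X.reshape(-1, training.X.shape[-1])
    return ScalerState(
        mins=flat.min(axis=0),
        maxs=flat.max(axis=0),
        channel_layout=training.channel_layout,
        fitted_from=training.source_trials,
    )


def apply_scaler(state: ScalerState | None, segments: SegmentSet) -> SegmentSet:
    """Affine map x -> (x - min) / (max - min), per channel, no clipping.

    Training data lands in [0, 1]; other folds may exceed that range.
    Constant channels map to 0.
    """
    if state is None or not isinstance(state, ScalerState):
        raise NotFittedError("scaler has not been fitted")
    span = state.maxs - state.mins
    safe = np.where(span > 0, span, 1.0)
    X = (segments.X - state.mins) / safe
    X = np.where(span > 0, X, 0.0).astype(np.float32)
    return SegmentSet(
        X=X,
        y=segments.y,
        sources=segments.sources,
        window_ordinals=segments.window_ordinals,
        channel_layout=segments.channel_layout,
        window_length=segments.window_length,
    )
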