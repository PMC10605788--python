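"""Reading and writing trial CSVs, manifests, and run configurations.

The canonical on-disk layout is one CSV per trial with columns named
``<site>_<channel>`` (e.g. ``shankR_Mag_X``) for each of the six sensor
sites' 22 channels, plus a ``manifest.csv`` listing participant, surface,
trial index, duration and file path.  Missing samples are empty cells.
Column mapping is name-based, so column order is irrelevant; unknown
columns are ignored with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CHANNEL_NAMES,
    N_CHANNELS_PER_SENSOR,
    GaitDataset,
    Site,
    Surface,
    Trial,
)

__all__ = [
    "SchemaError",
    "trial_filename",
    "write_trial_csv",
    "write_cohort",
    "read_trial_csv",
    "read_cohort",
    "RunConfig",
]


class SchemaError(ValueError):
    """A mandatory channel column could not be resolved."""


def trial_filename(trial: Trial) -> str:
    return (f"p{trial.participant_id:02d}_{trial.surface.name}"
            f"_t{trial.trial_index}.csv")


def write_trial_csv(trial: Trial, path: Path) -> None:
    """One CSV per trial, site-prefixed canonical channel headers."""
    cols = {}
    n = trial.n_samples
    for site in Site:
        m = trial.data.get(site)
        for ci, name in enumerate(CHANNEL_NAMES):
            col = m[:, ci] if m is not None else np.full(n, np.nan)
            cols[f"{site.name}_{name}"] = col
    # %.17g guarantees float64 text round-trips bit-exactly
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_cohort(dataset: GaitDataset, directory: Path) -> Path:
    """Write every trial plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in dataset:
        fname = trial_filename(trial)
        write_trial_csv(trial, directory / fname)
        rows.append({
            "participant": trial.participant_id,
            "surface": trial.surface.name,
            "trial": trial.trial_index,
            "duration_s": trial.duration_s,
            "n_samples": trial.n_samples,
            "path": fname,
        })
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_trial_csv(
    path: Path,
    participant_id: int,
    surface: Surface | str,
    trial_index: int,
    sample_rate: float = 100.0,
    site: Site | None = None,
) -> Trial:
    """Read one trial CSV into canonical channel order.

    Headers may be site-prefixed (``shankR_Mag_X``) or, for a
    single-sensor file with ``site`` given, bare channel names.  A site
    counts as recorded when any of its columns appear; it must then supply
    all 22 channels or a :class:`SchemaError` names the missing column.
    Missing values (empty cells) are preserved as NaN.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    surface = Surface[surface] if isinstance(surface, str) else Surface(surface)
    colmap: dict[Site, dict[str, str]] = {}
    unknown = []
    for col in df.columns:
        matched = False
        if site is not None and col in CHANNEL_NAMES:
            colmap.setdefault(Site(site), {})[col] = col
            matched = True
        else:
            for s in Site:
                prefix = f"{s.name}_"
                if col.startswith(prefix) and col[len(prefix):] in CHANNEL_NAMES:
                    colmap.setdefault(s, {})[col[len(prefix):]] = col
                    matched = True
                    break
        if not matched:
            unknown.append(col)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown column(s) {unknown}")
    if not colmap:
        raise SchemaError(f"{path}: no resolvable channel columns")
    data: dict[Site, np.ndarray] = {}
    for s, mapping in colmap.items():
        missing = [name for name in CHANNEL_NAMES if name not in mapping]
        if missing:
            label = missing[0] if site is not None else f"{s.name}_{missing[0]}"
            raise SchemaError(f"{path}: missing mandatory column {label}")
        mat = np.column_stack([df[mapping[name]].to_numpy(dtype=float)
                               for name in CHANNEL_NAMES])
        data[s] = mat
    return Trial(
        participant_id=participant_id,
        surface=surface,
        trial_index=trial_index,
        data=data,
        sample_rate=sample_rate,
    )


def read_cohort(directory: Path, sample_rate: float = 100.0) -> GaitDataset:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    trials = []
    for row in manifest.itertuples():
        trials.append(read_trial_csv(
            directory / row.path,
            participant_id=int(row.participant),
            surface=row.surface,
            trial_index=int(row.trial),
            sample_rate=sample_rate,
        ))
    return GaitDataset(trials=trials, provenance="on_disk")


@dataclass
class RunConfig:
    """Validated, serializable configuration of one experiment run."""

    groups: list[str] = field(default_factory=lambda: ["Acc"])
    sensors: list[str] = field(
        default_factory=lambda: ["shankL", "shankR"])
    window_length: int = 400
    window_lengths: list[int] | None = None  # for sweep mode
    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 32
    patience_stop: int = 25
    patience_lr: int = 10
    seed: int = 0
    mode: str = "single"  # single | select-signals | select-sensors | sweep-window

    def __post_init__(self) -> None:
        from .core import SIGNAL_GROUPS
        bad = [g for g in self.groups if g not in SIGNAL_GROUPS]
        if bad:
            raise ValueError(f"unknown signal group(s): {bad}")
        for s in self.sensors:
            Site[s]  # KeyError on unknown site
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")

    @property
    def site_list(self) -> list[Site]:
        return [Site[s] for s in self.sensors]

    def to_yaml(self, path: Path) -> None:
        payload = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)
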