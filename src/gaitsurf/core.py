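"""Shared vocabulary for the walking-surface classification pipeline.

Defines the nine surface conditions, the six inertial-sensor body sites,
the seven signal groups recorded by each sensor (22 channels total), and
the container types that flow between pipeline stages: labeled trials,
trial collections, and fixed-length windowed segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Surface",
    "Site",
    "SIGNAL_GROUPS",
    "SIGNAL_GROUP_ORDER",
    "CHANNEL_NAMES",
    "CHANNEL_INDEX",
    "N_CHANNELS_PER_SENSOR",
    "ChannelKey",
    "channel_layout",
    "Trial",
    "GaitDataset",
    "Segment",
    "SegmentSet",
    "InvalidConfigurationError",
]


class InvalidConfigurationError(ValueError):
    """Raised for duplicate/unknown signal groups or sensor sites."""


class Surface(IntEnum):
    """The nine walking-surface conditions, in canonical report order.

    FE: paved flat even; StrU/StrD: stairs up/down; SlpU/SlpD: slope
    up/down; GR: grass; BnkL/BnkR: surface banked left/right; CS: uneven
    cobblestone.  The integer value is the fixed class ordinal used on
    confusion-matrix axes.
    """

    FE = 0
    StrU = 1
    StrD = 2
    SlpU = 3
    SlpD = 4
    GR = 5
    BnkL = 6
    BnkR = 7
    CS = 8


class Site(IntEnum):
    """The six sensor body sites; the value is the canonical stacking rank."""

    wrist = 0
    thighR = 1
    thighL = 2
    shankR = 3
    shankL = 4
    trunk = 5


#: Signal groups and their channel names, in canonical per-sensor column order.
#: Acc: 3D acceleration; FreeAcc: gravity-subtracted acceleration; Gyr: rate
#: of turn; Mag: magnetic field; VelInc: per-sample velocity increment; Ori:
#: per-sample orientation-increment quaternion; YPR: yaw/pitch/roll Euler angles.
SIGNAL_GROUPS: dict[str, tuple[str, ...]] = {
    "Acc": ("Acc_X", "Acc_Y", "Acc_Z"),
    "FreeAcc": ("FreeAcc_X", "FreeAcc_Y", "FreeAcc_Z"),
    "Gyr": ("Gyr_X", "Gyr_Y", "Gyr_Z"),
    "Mag": ("Mag_X", "Mag_Y", "Mag_Z"),
    "VelInc": ("VelInc_X", "VelInc_Y", "VelInc_Z"),
    "Ori": ("OriInc_q0", "OriInc_q1", "OriInc_q2", "OriInc_q3"),
    "YPR": ("Yaw", "Pitch", "Roll"),
}

SIGNAL_GROUP_ORDER: tuple[str, ...] = tuple(SIGNAL_GROUPS)

CHANNEL_NAMES: tuple[str, ...] = tuple(
    name for group in SIGNAL_GROUP_ORDER for name in SIGNAL_GROUPS[group]
)
CHANNEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(CHANNEL_NAMES)}
N_CHANNELS_PER_SENSOR: int = len(CHANNEL_NAMES)  # 22


#: One column of an assembled input matrix: (signal group, sensor site, channel name).
ChannelKey = tuple[str, Site, str]


def channel_layout(
    groups: Sequence[str], sensors: Sequence[Site]
) -> list[ChannelKey]:
    """Column layout of a fused input matrix.

    The outer loop runs over signal groups in the order given by the caller
    (i.e. selection order), the inner loop over sensors in canonical site
    rank, then channels in canonical per-group order.  The layout is a pure
    function of its arguments, independent of any dataset.

    Parameters
    ----------
    groups : ordered signal-group names, no duplicates.
    sensors : ordered sensor sites, no duplicates.

    Returns
    -------
    list of (group, site, channel_name), one entry per matrix column.
    """
    if not groups or not sensors:
        raise InvalidConfigurationError("groups and sensors must be non-empty")
    if len(set(groups)) != len(groups):
        raise InvalidConfigurationError(f"duplicate signal group in {groups!r}")
    sensors = [Site(s) for s in sensors]
    if len(set(sensors)) != len(sensors):
        raise InvalidConfigurationError(f"duplicate sensor site in {sensors!r}")
    unknown = [g for g in groups if g not in SIGNAL_GROUPS]
    if unknown:
        raise InvalidConfigurationError(f"unknown signal group(s): {unknown}")
    ordered_sites = sorted(sensors, key=lambda s: s.value)
    layout: list[ChannelKey] = []
    for group in groups:
        for site in ordered_sites:
            for name in SIGNAL_GROUPS[group]:
                layout.append((group, site, name))
    return layout


TrialKey = tuple[int, Surface, int]


@dataclass
class Trial:
    """One labeled straight-walking recording.

    ``data`` maps each recorded sensor site to an ``[n_samples, 22]`` float
    matrix in canonical channel order (see :data:`CHANNEL_NAMES`).  A site
    may be absent entirely, or present as an all-NaN matrix (a fully missing
    recording); both are treated as missing downstream.
    """

    participant_id: int
    surface: Surface
    trial_index: int
    data: dict[Site, np.ndarray]
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.participant_id < 1:
            raise ValueError("participant_id must be >= 1")
        self.surface = Surface(self.surface)
        lengths = {m.shape[0] for m in self.data.values()}
        if len(lengths) > 1:
            raise ValueError(f"sensor matrices disagree on n_samples: {lengths}")
        for site, m in self.data.items():
            if m.ndim != 2 or m.shape[1] != N_CHANNELS_PER_SENSOR:
                raise ValueError(
                    f"{Site(site).name}: expected [n, {N_CHANNELS_PER_SENSOR}] "
                    f"matrix, got {m.shape}"
                )

    @property
    def key(self) -> TrialKey:
        return (self.participant_id, self.surface, self.trial_index)

    @property
    def n_samples(self) -> int:
        for m in self.data.values():
            return int(m.shape[0])
        return 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def sensor_missing(self, site: Site) -> bool:
        """True if the site was not recorded or its whole matrix is NaN."""
        m = self.data.get(Site(site))
        return m is None or bool(np.isnan(m).all())


@dataclass
class GaitDataset:
    """A collection of trials with unique (participant, surface, trial) keys."""

    trials: list[Trial]
    provenance: str = "synthetic"  # "synthetic" | "on_disk"

    def __post_init__(self) -> None:
        keys = [t.key for t in self.trials]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (participant, surface, trial_index) keys")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    @property
    def keys(self) -> list[TrialKey]:
        return [t.key for t in self.trials]


@dataclass
class Segment:
    """A single fixed-length window cut from one trial."""

    matrix: np.ndarray  # [L, C]
    label: Surface
    source: TrialKey
    window_ordinal: int


@dataclass
class SegmentSet:
    """Windowed input matrices with labels and trial provenance.

    Stored densely: ``X`` is ``[n_segments, L, C]``, ``y`` the class
    ordinals, ``sources`` the originating trial key per segment.  All
    segments share the window length and channel layout.
    """

    X: np.ndarray
    y: np.ndarray
    sources: list[TrialKey]
    window_ordinals: np.ndarray
    channel_layout: list[ChannelKey]
    window_length: int

    def __post_init__(self) -> None:
        if self.X.ndim != 3:
            raise ValueError("X must be [n, L, C]")
        n, L, C = self.X.shape
        if L != self.window_length or C != len(self.channel_layout):
            raise ValueError("X shape inconsistent with layout/window length")
        if len(self.y) != n or len(self.sources) != n:
            raise ValueError("labels/sources length mismatch")

    def __len__(self) -> int:
        return int(self.X.shape[0])

    @property
    def segments(self) -> list[Segment]:
        return [
            Segment(self.X[i], Surface(int(self.y[i])), self.sources[i],
                    int(self.window_ordinals[i]))
            for i in range(len(self))
        ]

    @property
    def source_trials(self) -> set[TrialKey]:
        return set(self.sources)

    def subset(self, mask: np.ndarray) -> "SegmentSet":
        idx = np.flatnonzero(mask)
        return SegmentSet(
            X=self.X[idx],
            y=self.y[idx],
            sources=[self.sources[i] for i in idx],
            window_ordinals=self.window_ordinals[idx],
            channel_layout=self.channel_layout,
            window_length=self.window_length,
        )

    def subset_by_trials(self, keys: Iterable[TrialKey]) -> "SegmentSet":
        keyset = set(keys)
        mask = np.array([s in keyset for s in self.sources], dtype=bool)
        return self.subset(mask)
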