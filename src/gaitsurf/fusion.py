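"""Assemble fused, windowed 2D input matrices for the network.

Signal fusion stacks the selected signal groups from the selected sensor
sites column-wise (selection order over groups, canonical rank over
sites), then cuts each usable trial into non-overlapping windows of L
samples.  A window is one classifier input of shape [L, C]; e.g. the Acc
group from both shanks gives C = 6.
"""

from __future__ import annotations

import numpy as np

from .core import (
    CHANNEL_INDEX,
    GaitDataset,
    SegmentSet,
    Site,
    channel_layout,
)
from .preprocess import drop_unusable, fill_missing, segment_matrix

__all__ = ["EmptyDatasetError", "assemble_segments"]


class EmptyDatasetError(ValueError):
    """No usable trial produced any segment."""


def assemble_segments(
    dataset: GaitDataset,
    groups: list[str],
    sensors: list[Site],
    window_length: int,
    repair_missing: bool = True,
) -> SegmentSet:
    """Build the SegmentSet for a (groups, sensors, L) configuration.

    Trials lacking any requested sensor are excluded (with the spirit of a
    complete-removal policy for fully missing recordings); remaining point
    gaps are repaired by the nearest-value fill when ``repair_missing``.
    The dataset is expected to be smoothed already (see
    :func:`gaitsurf.preprocess.filter_dataset`).
    """
    layout = channel_layout(groups, sensors)
    usable, _dropped = drop_unusable(dataset, sensors)
    cols_per_site: dict[Site, list[int]] = {}
    order: list[tuple[Site, int]] = [
        (site, CHANNEL_INDEX[name]) for (_g, site, name) in layout
    ]

    xs, ys, sources, ordinals = [], [], [], []
    for trial in usable:
        mat = np.column_stack([trial.data[site][:, ci] for site, ci in order])
        if repair_missing and np.isnan(mat).any():
            mat = fill_missing(mat)
        windows = segment_matrix(mat, window_length)
        for w, win in enumerate(windows):
            xs.append(win)
            ys.append(int(trial.surface))
            sources.append(trial.key)
            ordinals.append(w)
    if not xs:
        raise EmptyDatasetError(
            f"no usable segments for groups={groups}, sensors="
            f"{[Site(s).name for s in sensors]}, L={window_length}")
    X = np.stack(xs).astype(np.float32)
    return SegmentSet(
        X=X,
        y=np.asarray(ys, dtype=np.int64),
        sources=sources,
        window_ordinals=np.asarray(ordinals, dtype=np.int64),
        channel_layout=layout,
        window_length=window_length,
    )
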