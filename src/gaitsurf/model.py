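"""The 25-layer 1D-CNN surface classifier.

Five convolutional blocks followed by a flatten and a 9-way softmax dense
layer.  Each block is convolution (kernel 3, stride 1, "same" padding) ->
ReLU -> batch normalization -> max pooling (size 3, stride 3); blocks 3-5
append a dropout layer (rate 0.5).  The filter schedule is
64, 64, 128, 128, 128.  Layer count: 4 + 4 + 5 + 5 + 5 + 2 = 25.

Pooling length arithmetic is ceil-mode by default ("same"-style padding),
which keeps every window length from 100 to 500 samples valid through all
five pools (100 -> 34 -> 12 -> 4 -> 2 -> 1); floor-mode ("valid")
arithmetic is available via ``pool_mode="floor"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "FILTER_SCHEDULE",
    "InvalidShapeError",
    "ModelSpec",
    "ModelHandle",
    "temporal_lengths",
    "build_surface_cnn",
    "count_parameters",
    "layer_manifest",
]

FILTER_SCHEDULE = (64, 64, 128, 128, 128)
KERNEL_SIZE = 3
POOL_SIZE = 3
DROPOUT_RATE = 0.5
DROPOUT_BLOCKS = (3, 4, 5)  # 1-based block numbers with a trailing dropout


class InvalidShapeError(ValueError):
    """Input too short to survive the five pooling stages."""


@dataclass(frozen=True)
class ModelSpec:
    """Buildable manifest of the architecture for a given input shape."""

    window_length: int
    n_channels: int
    n_classes: int = 9
    filters: tuple[int, ...] = FILTER_SCHEDULE
    kernel_size: int = KERNEL_SIZE
    pool_size: int = POOL_SIZE
    dropout_rate: float = DROPOUT_RATE
    pool_mode: str = "ceil"

    @property
    def n_layers(self) -> int:
        return 4 * 2 + 5 * len(DROPOUT_BLOCKS) + 2


def temporal_lengths(window_length: int, pool_mode: str = "ceil",
                     n_blocks: int = 5) -> list[int]:
    """Temporal length after each block's pooling stage."""
    lengths = []
    n = window_length
    for _ in range(n_blocks):
        n = nn.pooled_length(n, POOL_SIZE, pool_mode)
        lengths.append(n)
    return lengths


@dataclass
class ModelHandle:
    """A built (possibly trained) network plus its spec and manifest."""

    network: nn.Network
    spec: ModelSpec
    manifest: list[str]

    @property
    def parameter_count(self) -> int:
        return self.network.n_trainable() + self.network.n_non_trainable()


def build_surface_cnn(
    window_length: int,
    n_channels: int,
    n_classes: int = 9,
    pool_mode: str = "ceil",
    seed: int = 0,
) -> ModelHandle:
    """Build the 25-layer classifier for an [L, C] input.

    Raises :class:`InvalidShapeError` if the window is too short for five
    pooling stages under the chosen pooling arithmetic.
    """
    if n_channels < 1:
        raise InvalidShapeError("need at least one channel")
    lengths = temporal_lengths(window_length, pool_mode)
    if lengths[-1] < 1:
        raise InvalidShapeError(
            f"window of {window_length} samples collapses to length "
            f"{lengths[-1]} after five pools (mode={pool_mode})")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = n_channels
    for block, filters in enumerate(FILTER_SCHEDULE, start=1):
        layers.append(nn.Conv1D(in_ch, filters, KERNEL_SIZE, rng))
        layers.append(nn.ReLU())
        layers.append(nn.BatchNorm(filters))
        layers.append(nn.MaxPool1D(POOL_SIZE, mode=pool_mode))
        if block in DROPOUT_BLOCKS:
            layers.append(nn.Dropout(DROPOUT_RATE, rng))
        in_ch = filters
    layers.append(nn.Flatten())
    layers.append(nn.Dense(lengths[-1] * FILTER_SCHEDULE[-1], n_classes, rng))
    net = nn.Network(layers)
    spec = ModelSpec(window_length=window_length, n_channels=n_channels,
                     n_classes=n_classes, pool_mode=pool_mode)
    manifest = [layer.describe() for layer in net.layers]
    assert len(manifest) == spec.n_layers == 25
    return ModelHandle(network=net, spec=spec, manifest=manifest)


def count_parameters(handle: ModelHandle) -> int:
    """Trainable + non-trainable (batch-norm statistics) parameter count."""
    return handle.parameter_count


def layer_manifest(handle: ModelHandle) -> list[str]:
    """Ordered human-readable layer descriptions (length 25)."""
    return list(handle.manifest)
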