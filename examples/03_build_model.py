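"""Build the 25-layer surface classifier and inspect its arithmetic.

Shows the layer manifest, the temporal-length chain through the five
pooling stages, and parameter totals for several input shapes, including
the floor-pooling variant.
"""

import numpy as np

from gaitsurf.model import (
    build_surface_cnn,
    count_parameters,
    layer_manifest,
    temporal_lengths,
)

handle = build_surface_cnn(400, 6)
manifest = layer_manifest(handle)
print(f"layers: {len(manifest)}")
for i, desc in enumerate(manifest, start=1):
    print(f"  {i:2d}  {desc}")

print(f"\ntemporal lengths, L=100, ceil pooling: {temporal_lengths(100)}")
print(f"temporal lengths, L=400, ceil pooling: {temporal_lengths(400)}")

for L, C in [(400, 6), (400, 30), (100, 12)]:
    n = count_parameters(build_surface_cnn(L, C))
    print(f"parameters for {L} x {C} input: {n:,}")
n_floor = count_parameters(build_surface_cnn(400, 6, pool_mode="floor"))
print(f"parameters for 400 x 6, floor pooling: {n_floor:,} "
      "(flattens to 128 features)")

x = np.random.default_rng(0).normal(size=(2, 400, 6)).astype(np.float32)
proba = handle.network.predict_proba(x)
print(f"\nsoftmax head: probabilities sum to {proba.sum(axis=1)}")
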