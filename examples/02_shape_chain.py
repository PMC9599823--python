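"""Trace the 9-layer stream's shape algebra and confirm it with a forward pass.

Each conv/pool layer maps extent I to floor((I + 2P - D(K-1) - 1)/S + 1)
per axis (P = 0, D = 1 throughout). Iterated over the printed schedule from
a (50, 64, 64) input, the grid collapses to exactly 1 x 1 x 1 with 8
channels — which is why the per-ROI feature vector is simply the flattened
final activation.
"""

import numpy as np

import gcndecode as g

cfg = g.StreamConfig()  # default 9 layers, feature width 8
chain = g.shape_chain(cfg)
kinds = [spec.kind for spec in cfg.layer_specs()]

print(f"input grid (depth, h, w): {chain[0]}")
for kind, extents in zip(kinds, chain[1:]):
    print(f"  after {kind:9s} -> {extents}")

stream = g.build_stream(cfg)
x = np.random.default_rng(0).normal(size=(1, 3, 50, 64, 64)).astype(np.float32)
observed = stream.layer_output_shapes(x)
print("forward-pass shapes agree layer by layer:",
      [s[2:] for s in observed] == chain[1:])
print(f"feature vector length: {stream.out_features} "
      "(8 channels on a 1x1x1 grid, flattened)")
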