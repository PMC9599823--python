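"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import gcndecode as g

TINY_GRID = (6, 8, 8)
SMALL_GRID = (10, 12, 12)

#: A stream small enough for sub-second training steps on the tiny grid:
#: one conv/BN/ReLU plus an overlapping pool, 4-channel head.
TINY_LAYERS = [
    g.LayerSpec("conv3d", (3, 3, 3), (1, 1, 1), 4),
    g.LayerSpec("maxpool3d", (3, 3, 3), (2, 2, 2)),
]


@pytest.fixture(scope="session")
def template():
    return g.generate_template(seed=7, grid=TINY_GRID)


@pytest.fixture(scope="session")
def full_template():
    """Template on the full 50 x 64 x 64 acquisition grid."""
    return g.generate_template(seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(template):
    """2 subjects x 4 classes x 3 reps on the tiny grid."""
    cfg = g.GeneratorConfig(
        n_subjects=2, scans_per_class_per_subject=3, n_classes=4,
        effect_size=2.0, seed=7, grid=TINY_GRID,
    )
    return g.generate_dataset(cfg, template)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_stream_config():
    return g.StreamConfig(layers=TINY_LAYERS, feature_width=4,
                          input_grid=TINY_GRID)
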