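"""Per-ROI 3D-CNN feature streams and the closed-form output-size calculator.

One stream maps a masked 3-frame fMRI block (3 channels on a depth x height x
width grid) to a short feature vector. The default architecture has 9 layers
in the main structure — six valid convolutions (each followed by batch norm
and ReLU) and three overlapping max-pools — whose kernel/stride schedule
collapses the default 50 x 64 x 64 grid to exactly 1 x 1 x 1 with 8 channels,
so the feature vector is the flattened final activation with no extra head.

Each of the eleven ROIs gets its own stream (same architecture, independent
weights by default); stacking the eleven vectors in canonical ROI order gives
the node-feature matrix consumed by the graph classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .rois import ROI_NAMES, ROITemplate, apply_mask

Triple = tuple[int, int, int]


class InfeasibleArchitectureError(ValueError):
    """A layer would produce a non-positive spatial extent."""


@dataclass(frozen=True)
class LayerSpec:
    """One conv or pool layer: kind, kernel, stride; padding 0, dilation 1.

    Convolutions use stride 1; pools stride 2 — the only combinations the
    architecture employs. ``out_channels`` applies to convolutions only.
    """

    kind: str  # "conv3d" | "maxpool3d"
    kernel: Triple
    stride: Triple
    out_channels: int | None = None

    def __post_init__(self):
        if self.kind not in ("conv3d", "maxpool3d"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv3d" and self.out_channels is None:
            raise ValueError("conv3d layer needs out_channels")


def _conv(kernel: Triple, out_channels: int) -> LayerSpec:
    return LayerSpec("conv3d", kernel, (1, 1, 1), out_channels)


def _pool(kernel: Triple = (3, 3, 3), stride: Triple = (2, 2, 2)) -> LayerSpec:
    return LayerSpec("maxpool3d", kernel, stride)


def default9_layers(feature_width: int = 8) -> list[LayerSpec]:
    """The printed 9-layer schedule: C1 C2 S1 C3 C4 S2 C5 C6 S3.

    Kernels 3x5x5 for C1–C5 and 3x3x3 for C6; channels 16, 16, 32, 64, 64,
    then ``feature_width`` (8 by default; 2–12 for the width sweep).
    """
    return [
        _conv((3, 5, 5), 16),
        _conv((3, 5, 5), 16),
        _pool(),
        _conv((3, 5, 5), 32),
        _conv((3, 5, 5), 64),
        _pool(),
        _conv((3, 5, 5), 64),
        _conv((3, 3, 3), feature_width),
        _pool(),
    ]


def small_layers(feature_width: int = 8) -> list[LayerSpec]:
    """Reduced-grid stream for the (10, 12, 12) grid: C C S C with 3x3x3 kernels.

    Mirrors the default design (cascaded small kernels, overlapping pool,
    feature_width-channel final conv collapsing the grid to 1x1x1) at a size
    where whole-pipeline experiments run in minutes on one CPU.
    """
    return [
        _conv((3, 3, 3), 8),
        _conv((3, 3, 3), 8),
        _pool(),
        _conv((2, 3, 3), feature_width),
    ]


def depth_sweep_layers(n_layers: int, feature_width: int = 8) -> list[LayerSpec]:
    """Layer schedules for the depth sweep (6–11 layers in the main structure).

    The 9-layer entry is the printed default. The others follow the same
    design rules (cascaded 3x5x5 / 3x3x3 convolutions, overlapping pools,
    final conv carrying ``feature_width`` channels); the 10- and 11-layer
    variants need anisotropic late kernels to stay feasible on 50 x 64 x 64.
    """
    if n_layers == 6:  # 3 conv + 3 pool
        return [_conv((3, 5, 5), 16), _pool(), _conv((3, 5, 5), 32), _pool(),
                _conv((3, 3, 3), feature_width), _pool()]
    if n_layers == 7:  # 4 conv + 3 pool
        return [_conv((3, 5, 5), 16), _conv((3, 5, 5), 16), _pool(),
                _conv((3, 5, 5), 32), _pool(), _conv((3, 3, 3), feature_width), _pool()]
    if n_layers == 8:  # 5 conv + 3 pool
        return [_conv((3, 5, 5), 16), _conv((3, 5, 5), 16), _pool(),
                _conv((3, 5, 5), 32), _conv((3, 5, 5), 64), _pool(),
                _conv((3, 3, 3), feature_width), _pool()]
    if n_layers == 9:
        return default9_layers(feature_width)
    if n_layers == 10:  # 6 conv + 4 pool
        return [_conv((3, 5, 5), 16), _conv((1, 5, 5), 16), _pool(),
                _conv((3, 5, 5), 32), _conv((1, 3, 3), 64), _pool(),
                _conv((3, 3, 3), 64), _pool(), _conv((1, 1, 1), feature_width), _pool()]
    if n_layers == 11:  # 7 conv + 4 pool
        return [_conv((3, 5, 5), 16), _conv((1, 5, 5), 16), _pool(),
                _conv((3, 5, 5), 32), _conv((1, 3, 3), 32), _pool(),
                _conv((3, 3, 3), 64), _pool(), _conv((1, 1, 1), 64),
                _pool(), _conv((1, 1, 1), feature_width)]
    raise ValueError(f"no preset for {n_layers} layers (supported: 6..11)")


LAYER_PRESETS = {
    "default9": default9_layers,
    "small": small_layers,
}


@dataclass
class StreamConfig:
    """Configuration of one feature stream.

    ``layers`` may be a preset name ("default9", "small") or an explicit list
    of :class:`LayerSpec`. ``feature_width`` is the final channel count (the
    feature-vector length when the grid collapses to 1x1x1); default 8,
    sweepable 2–12. ``in_channels`` is the number of time frames.
    """

    layers: str | list[LayerSpec] = "default9"
    feature_width: int = 8
    in_channels: int = 3
    shared_weights: bool = False
    seed: int = 0
    input_grid: Triple = (50, 64, 64)

    def layer_specs(self) -> list[LayerSpec]:
        if isinstance(self.layers, str):
            try:
                return LAYER_PRESETS[self.layers](self.feature_width)
            except KeyError:
                raise ValueError(f"unknown layer preset {self.layers!r}") from None
        return list(self.layers)


def output_size(I: int, P: int, D: int, K: int, S: int) -> int:
    """Output extent of a valid conv/pool along one axis.

    C = floor((I + 2P - D*(K - 1) - 1) / S + 1), the standard no-padding
    formula with dilation D; here P = 0 and D = 1 throughout.
    """
    if I <= 0 or K <= 0 or S <= 0 or D <= 0 or P < 0:
        raise ValueError("extents, kernel, stride, dilation must be positive; padding >= 0")
    c = (I + 2 * P - D * (K - 1) - 1) // S + 1
    if c < 1:
        raise InfeasibleArchitectureError(
            f"output extent {c} < 1 for I={I}, P={P}, D={D}, K={K}, S={S}"
        )
    return c


def shape_chain(config: StreamConfig, input_extents: Triple | None = None) -> list[Triple]:
    """Per-layer spatial extents, starting with the input grid.

    Applies :func:`output_size` axis-by-axis through the layer schedule;
    raises :class:`InfeasibleArchitectureError` naming the offending layer if
    any axis would collapse below 1.
    """
    extents = tuple(input_extents if input_extents is not None else config.input_grid)
    chain = [extents]
    for li, spec in enumerate(config.layer_specs()):
        try:
            extents = tuple(
                output_size(extents[ax], 0, 1, spec.kernel[ax], spec.stride[ax])
                for ax in range(3)
            )
        except InfeasibleArchitectureError as e:
            raise InfeasibleArchitectureError(
                f"layer {li} ({spec.kind} kernel {spec.kernel}): {e}"
            ) from None
        chain.append(extents)
    return chain


class FeatureStream:
    """A built stream: masked volume sequence in, feature vector out."""

    def __init__(self, config: StreamConfig, rng: np.random.Generator):
        self.config = config
        chain = shape_chain(config)  # validates feasibility before building
        self.final_grid = chain[-1]
        layers: list[nn.Layer] = []
        in_ch = config.in_channels
        for li, spec in enumerate(config.layer_specs()):
            if spec.kind == "conv3d":
                # the first layer's input is data: its input gradient is never used
                layers.append(nn.Conv3d(in_ch, spec.out_channels, spec.kernel, rng,
                                        needs_input_grad=li > 0))
                layers.append(nn.BatchNorm(spec.out_channels, feature_axis=1))
                layers.append(nn.ReLU())
                in_ch = spec.out_channels
            else:
                layers.append(nn.MaxPool3d(spec.kernel, spec.stride))
        layers.append(nn.Flatten())
        self.net = nn.Sequential(layers)
        self.out_features = in_ch * int(np.prod(self.final_grid))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(x, training)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def layer_output_shapes(self, x: np.ndarray) -> list[tuple[int, ...]]:
        """Observed activation shape after each conv/pool layer (shape oracle)."""
        shapes = []
        for layer in self.net.layers:
            x = layer.forward(x, training=False)
            if isinstance(layer, (nn.Conv3d, nn.MaxPool3d)):
                shapes.append(x.shape)
        return shapes


def build_stream(config: StreamConfig, rng: np.random.Generator | None = None) -> FeatureStream:
    """Build one trainable feature stream; raises before training if infeasible."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return FeatureStream(config, rng)


def build_streams(config: StreamConfig, n_streams: int = len(ROI_NAMES),
                  rng: np.random.Generator | None = None) -> list[FeatureStream]:
    """One stream per ROI. Independent weights unless ``config.shared_weights``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.shared_weights:
        return [build_stream(config, rng)] * n_streams
    return [build_stream(config, rng) for _ in range(n_streams)]


def extract_feature_matrix(streams: list[FeatureStream], scan_data: np.ndarray,
                           template: ROITemplate) -> np.ndarray:
    """Stack one stream output per ROI into the node-feature matrix.

    Row r is streams[r] applied to the scan masked to ROI r, rows in canonical
    ROI order — an 11 x 8 matrix under the defaults.
    """
    if len(streams) != len(ROI_NAMES):
        raise ValueError(f"need {len(ROI_NAMES)} streams, got {len(streams)}")
    rows = []
    for name, stream in zip(ROI_NAMES, streams):
        masked = apply_mask(scan_data, name, template)
        rows.append(stream.forward(masked[None], training=False)[0])
    return np.stack(rows)
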