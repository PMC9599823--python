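"""Residual graph convolutional classifier over the ROI graph.

The propagation rule per layer is

    H^(l+1) = sigma( D~^{-1/2} (A + I) D~^{-1/2} H^(l) W^(l) ),  sigma = ReLU,

with node features H (eleven ROIs x feature width) and the fixed normalized
functional-connectivity matrix. The network stacks five blocks of
dropout(0.5) -> graph convolution -> batch norm -> ReLU; residual skips
(type B by default) let the stack go deep without the node features
collapsing to a common value (over-smoothing). A single dense layer over the
flattened node features produces the 10 class scores.

Residual wirings, with Z = BN(A_hat . dropout(H) . W):

    type A:    H_out = ReLU(Z) + H
    type B:    H_out = ReLU(Z + H)          (pre-activation addition; default)
    type C:    H_out = ReLU(Z + H P)        with trainable projection P
    none:      H_out = ReLU(Z)              (the no-residual ablation)

Residual wiring over a graph-conv block can be realized several ways;
A/B/C are this package's concrete definitions. P is initialized
to the identity so type C starts where type B starts but may learn to rescale
the skip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .rois import ROI_NAMES

RESIDUAL_TYPES = ("A", "B", "C", "none")


def gcn_layer(H: np.ndarray, A_hat: np.ndarray, W: np.ndarray) -> np.ndarray:
    """The bare propagation primitive: ReLU(A_hat @ H @ W).

    Standalone form of the spectral graph-convolution rule; inside a residual
    block, batch norm and the skip addition are interposed before the ReLU.
    """
    H = np.asarray(H, dtype=np.float64)
    A_hat = np.asarray(A_hat, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if A_hat.shape[0] != A_hat.shape[1] or A_hat.shape[1] != H.shape[0]:
        raise ValueError(f"A_hat {A_hat.shape} incompatible with H {H.shape}")
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"H {H.shape} incompatible with W {W.shape}")
    return np.maximum(A_hat @ H @ W, 0.0)


@dataclass
class GCNConfig:
    """Graph-classifier configuration.

    ``width`` is the node-feature width carried through all blocks (constant,
    so identity skips always type-check); it must match the CNN streams'
    feature width. ``n_nodes`` is the ROI count.
    """

    n_blocks: int = 5
    residual_type: str = "B"
    width: int = 8
    dropout: float = 0.5
    n_classes: int = 10
    n_nodes: int = len(ROI_NAMES)
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.residual_type not in RESIDUAL_TYPES:
            raise ValueError(
                f"residual_type must be one of {RESIDUAL_TYPES}, got {self.residual_type!r}"
            )


class ResidualGCNBlock(nn.Layer):
    """dropout -> graph conv -> batch norm -> (skip) -> ReLU."""

    def __init__(self, width: int, a_hat: np.ndarray, residual_type: str,
                 dropout: float, rng: np.random.Generator):
        if residual_type not in RESIDUAL_TYPES:
            raise ValueError(f"unknown residual type {residual_type!r}")
        self.residual_type = residual_type
        self.drop = nn.Dropout(dropout, rng)
        self.gconv = nn.GraphConv(width, width, a_hat, rng)
        self.bn = nn.BatchNorm(width, feature_axis=-1)
        self.proj = None
        if residual_type == "C":
            self.proj = nn.Param(np.eye(width))
        self._cache = None

    def forward(self, x, training):
        z = self.bn.forward(
            self.gconv.forward(self.drop.forward(x, training), training), training
        )
        if self.residual_type == "B":
            s = z + x
            out = np.maximum(s, 0.0)
            self._cache = ("B", s > 0)
        elif self.residual_type == "A":
            out = np.maximum(z, 0.0) + x
            self._cache = ("A", z > 0)
        elif self.residual_type == "C":
            s = z + x @ self.proj.value
            out = np.maximum(s, 0.0)
            self._cache = ("C", s > 0, x)
        else:  # none
            out = np.maximum(z, 0.0)
            self._cache = ("none", z > 0)
        return out

    def _main_backward(self, gz):
        return self.drop.backward(self.gconv.backward(self.bn.backward(gz)))

    def backward(self, gy):
        kind = self._cache[0]
        if kind == "B":
            _, pos = self._cache
            g = gy * pos
            gx = self._main_backward(g) + g
        elif kind == "A":
            _, pos = self._cache
            gx = self._main_backward(gy * pos) + gy
        elif kind == "C":
            _, pos, x = self._cache
            g = gy * pos
            self.proj.grad += np.einsum("bnw,bnk->wk", x, g, optimize=True)
            gx = self._main_backward(g) + g @ self.proj.value.T
        else:
            _, pos = self._cache
            gx = self._main_backward(gy * pos)
        self._cache = None
        return gx

    def params(self):
        ps = self.drop.params() + self.gconv.params() + self.bn.params()
        if self.proj is not None:
            ps = ps + [self.proj]
        return ps


class GCNClassifier:
    """Stacked residual blocks plus the dense classification head.

    Input: node-feature matrices (batch, n_nodes, width); output: class
    scores (batch, n_classes), unnormalized — the loss applies softmax.
    """

    def __init__(self, config: GCNConfig, a_hat: np.ndarray,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(config.seed)
        a_hat = np.asarray(a_hat, dtype=np.float64)
        if a_hat.shape != (config.n_nodes, config.n_nodes):
            raise ValueError(
                f"A_hat shape {a_hat.shape} != ({config.n_nodes}, {config.n_nodes})"
            )
        self.config = config
        self.blocks = [
            ResidualGCNBlock(config.width, a_hat, config.residual_type,
                             config.dropout, rng)
            for _ in range(config.n_blocks)
        ]
        self.flatten = nn.Flatten()
        self.head = nn.Linear(config.n_nodes * config.width, config.n_classes, rng)

    def forward(self, feats: np.ndarray, training: bool = False) -> np.ndarray:
        x = feats
        for block in self.blocks:
            x = block.forward(x, training)
        return self.head.forward(self.flatten.forward(x, training), training)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.flatten.backward(self.head.backward(gy))
        for block in reversed(self.blocks):
            g = block.backward(g)
        return g

    def params(self) -> list[nn.Param]:
        ps = []
        for block in self.blocks:
            ps.extend(block.params())
        return ps + self.head.params()


def build_gcn(config: GCNConfig, a_hat: np.ndarray,
              rng: np.random.Generator | None = None) -> GCNClassifier:
    """Build the classifier; raises on invalid residual/width combinations."""
    return GCNClassifier(config, a_hat, rng)
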