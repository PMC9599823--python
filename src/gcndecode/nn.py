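"""Minimal neural-network engine: numpy layers with hand-written backprop.

Implements exactly the layer zoo the decoder needs — valid (no-padding) 3D
convolution, overlapping 3D max-pooling, batch normalization, ReLU, inverted
dropout, dense layers, and graph convolution — plus Adam with L2 weight decay
and softmax cross-entropy. Layers cache what their backward pass needs; a
``Sequential`` chains them. Everything is deterministic given the
``numpy.random.Generator`` handed to each stochastic piece.

Conventions: convolutional activations are (batch, channels, depth, height,
width); node-feature activations are (batch, nodes, features).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # whether weight decay applies (not for biases/BN)


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Seeded uniform fan-in initialization: U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv3d(Layer):
    """Valid 3D convolution (cross-correlation), stride 1, no padding, no dilation."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int], rng: np.random.Generator,
                 needs_input_grad: bool = True):
        self.kernel = tuple(kernel)
        self.in_channels = in_channels
        self.needs_input_grad = needs_input_grad
        fan_in = in_channels * int(np.prod(kernel))
        self.W = Param(uniform_fan_in(rng, (out_channels, in_channels) + self.kernel, fan_in))
        self.b = Param(uniform_fan_in(rng, (out_channels,), fan_in), decay=False)
        self._cache = None

    def _im2col(self, w, d0, d1):
        # (B, C, ds, oH, oW, kD, kH, kW) -> contiguous (B, ds, oH, oW, C, kD, kH, kW)
        return np.ascontiguousarray(np.moveaxis(w[:, :, d0:d1], 1, 4))

    def forward(self, x, training):
        # windows: (B, C, oD, oH, oW, kD, kH, kW) — a strided view, no copy
        w = sliding_window_view(x, self.kernel, axis=(2, 3, 4))
        B, C, oD, oH, oW = w.shape[:5]
        out_ch = self.W.value.shape[0]
        k3 = int(np.prod(self.kernel))
        Wm = self.W.value.reshape(out_ch, -1).astype(x.dtype, copy=False)
        bias = self.b.value.astype(x.dtype, copy=False)
        if training:
            # cache the full column matrix; backward is two BLAS matmuls
            cols = self._im2col(w, 0, oD)
            self._cache = (cols, oH, oW)
            y = cols.reshape(B * oD * oH * oW, C * k3) @ Wm.T
            y = y.reshape(B, oD, oH, oW, out_ch).transpose(0, 4, 1, 2, 3)
        else:
            # inference may see large grids: im2col in depth slabs (bounded copy)
            y = np.empty((B, out_ch, oD, oH, oW), dtype=x.dtype)
            slab = max(1, int(2**24 // max(1, B * C * k3 * oH * oW)))
            for d0 in range(0, oD, slab):
                cols = self._im2col(w, d0, d0 + slab)
                ds = cols.shape[1]
                out = cols.reshape(B * ds * oH * oW, C * k3) @ Wm.T
                y[:, :, d0:d0 + slab] = out.reshape(B, ds, oH, oW, out_ch).transpose(
                    0, 4, 1, 2, 3
                )
        return y + bias[None, :, None, None, None]

    def backward(self, gy):
        cols, oH, oW = self._cache
        B, oD = cols.shape[0], cols.shape[1]
        C = self.in_channels
        kD, kH, kW = self.kernel
        k3 = kD * kH * kW
        out_ch = self.W.value.shape[0]
        g = gy.transpose(0, 2, 3, 4, 1).reshape(B * oD * oH * oW, out_ch)
        self.W.grad += (g.T @ cols.reshape(B * oD * oH * oW, C * k3)).reshape(
            self.W.value.shape
        )
        self.b.grad += gy.sum(axis=(0, 2, 3, 4))
        if not self.needs_input_grad:
            self._cache = None
            return None
        Wm = self.W.value.reshape(out_ch, -1).astype(g.dtype, copy=False)
        gcols = (g @ Wm).reshape(B, oD, oH, oW, C, kD, kH, kW)
        # one contiguous reorder, then one dense add per kernel offset (col2im)
        gcols = np.ascontiguousarray(gcols.transpose(0, 4, 1, 2, 3, 5, 6, 7))
        gx = np.zeros((B, C, oD + kD - 1, oH + kH - 1, oW + kW - 1), dtype=gcols.dtype)
        for i in range(kD):
            for j in range(kH):
                for k in range(kW):
                    gx[:, :, i:i + oD, j:j + oH, k:k + oW] += gcols[..., i, j, k]
        self._cache = None
        return gx

    def params(self):
        return [self.W, self.b]


class MaxPool3d(Layer):
    """3D max pooling; default overlapping 3x3x3 kernel with stride 2."""

    def __init__(self, kernel: tuple[int, int, int] = (3, 3, 3),
                 stride: tuple[int, int, int] = (2, 2, 2)):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self._cache = None

    def forward(self, x, training):
        kD, kH, kW = self.kernel
        sD, sH, sW = self.stride
        w = sliding_window_view(x, self.kernel, axis=(2, 3, 4))[:, :, ::sD, ::sH, ::sW]
        B, C, oD, oH, oW = w.shape[:5]
        flat = w.reshape(B, C, oD, oH, oW, -1)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg)
        return y

    def backward(self, gy):
        x_shape, arg = self._cache
        B, C, D, H, W = x_shape
        oD, oH, oW = arg.shape[2:]
        kD, kH, kW = self.kernel
        sD, sH, sW = self.stride
        # recover (di, dj, dk) offsets of each window's argmax
        di, rem = np.divmod(arg, kH * kW)
        dj, dk = np.divmod(rem, kW)
        base_d = (np.arange(oD) * sD)[None, None, :, None, None]
        base_h = (np.arange(oH) * sH)[None, None, None, :, None]
        base_w = (np.arange(oW) * sW)[None, None, None, None, :]
        src_d = base_d + di
        src_h = base_h + dj
        src_w = base_w + dk
        flat_idx = (
            np.arange(B)[:, None, None, None, None] * (C * D * H * W)
            + np.arange(C)[None, :, None, None, None] * (D * H * W)
            + src_d * (H * W) + src_h * W + src_w
        )
        gx = np.zeros(B * C * D * H * W, dtype=gy.dtype)
        np.add.at(gx, flat_idx.ravel(), gy.ravel())
        self._cache = None
        return gx.reshape(x_shape)


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature axis.

    ``feature_axis=1`` covers conv activations (per channel); ``feature_axis=-1``
    covers node-feature matrices (per feature column across nodes and batch).
    Training uses batch statistics and updates running moments; inference uses
    the running moments.
    """

    def __init__(self, num_features: int, feature_axis: int = 1,
                 momentum: float = 0.1, eps: float = 1e-5):
        self.axis = feature_axis
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(num_features), decay=False)
        self.beta = Param(np.zeros(num_features), decay=False)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._cache = None

    def _shape(self, x):
        shape = [1] * x.ndim
        shape[self.axis] = x.shape[self.axis]
        return tuple(shape)

    def forward(self, x, training):
        sh = self._shape(x)
        axes = tuple(i for i in range(x.ndim) if i != self.axis % x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[self.axis]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype, copy=False)
        xhat = (x - mean.reshape(sh).astype(x.dtype, copy=False)) * inv_std.reshape(sh)
        if training:
            self._cache = (xhat, inv_std, axes, sh)
        return (self.gamma.value.astype(x.dtype, copy=False).reshape(sh) * xhat
                + self.beta.value.astype(x.dtype, copy=False).reshape(sh))

    def backward(self, gy):
        xhat, inv_std, axes, sh = self._cache
        n = gy.size // gy.shape[self.axis]
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g_xhat = gy * self.gamma.value.astype(gy.dtype, copy=False).reshape(sh)
        # standard batchnorm backward through batch statistics
        gx = (inv_std.reshape(sh) / n) * (
            n * g_xhat
            - g_xhat.sum(axis=axes).reshape(sh)
            - xhat * (g_xhat * xhat).sum(axis=axes).reshape(sh)
        )
        self._cache = None
        return gx

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        m = self._mask
        self._mask = None
        return gy * m


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        m = self._mask
        self._mask = None
        return gy * m


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = Param(uniform_fan_in(rng, (in_features, out_features), in_features))
        self.b = Param(uniform_fan_in(rng, (out_features,), in_features), decay=False)
        self._x = None

    def forward(self, x, training):
        self._x = x
        return (x @ self.W.value.astype(x.dtype, copy=False)
                + self.b.value.astype(x.dtype, copy=False))

    def backward(self, gy):
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        gx = gy @ self.W.value.T.astype(gy.dtype, copy=False)
        self._x = None
        return gx

    def params(self):
        return [self.W, self.b]


class GraphConv(Layer):
    """The spectral graph-convolution primitive: H -> A_hat @ H @ W.

    ``A_hat`` is the symmetric-normalized adjacency (fixed, non-trainable);
    inputs are batched node-feature matrices (batch, nodes, w_in).
    The nonlinearity is applied outside (the block interposes BN and the
    residual addition before ReLU).
    """

    def __init__(self, w_in: int, w_out: int, a_hat: np.ndarray, rng: np.random.Generator):
        self.a_hat = np.asarray(a_hat, dtype=np.float64)
        self.W = Param(uniform_fan_in(rng, (w_in, w_out), w_in))
        self._ah = None

    def forward(self, x, training):
        a = self.a_hat.astype(x.dtype, copy=False)
        ah = np.einsum("ij,bjw->biw", a, x, optimize=True)
        self._ah = ah
        return ah @ self.W.value.astype(x.dtype, copy=False)

    def backward(self, gy):
        self.W.grad += np.einsum("biw,bik->wk", self._ah, gy, optimize=True)
        g_ah = gy @ self.W.value.T.astype(gy.dtype, copy=False)
        gx = np.einsum("ij,bjw->biw", self.a_hat.T.astype(gy.dtype, copy=False),
                       g_ah, optimize=True)
        self._ah = None
        return gx

    def params(self):
        return [self.W]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over a batch and its gradient w.r.t. scores.

    ``labels`` are 0-based class indices. Equivalent to H(p, q) = -sum p log q
    with one-hot p and q = softmax(scores).
    """
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= scores.shape[-1]:
        raise ValueError("label index out of range")
    q = softmax(scores)
    n = scores.shape[0]
    loss = float(-np.log(q[np.arange(n), labels] + 1e-300).mean())
    grad = q.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam with classic L2 weight decay added to the gradient."""

    def __init__(self, params: list[Param], lr: float = 0.01, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def collect_batchnorms(root) -> list[BatchNorm]:
    """All BatchNorm instances reachable from a model/layer object."""
    found: list[BatchNorm] = []
    seen: set[int] = set()

    def walk(obj):
        if id(obj) in seen:
            return
        seen.add(id(obj))
        if isinstance(obj, BatchNorm):
            found.append(obj)
            return
        if isinstance(obj, (list, tuple)):
            for item in obj:
                walk(item)
            return
        for attr in ("layers", "blocks", "streams", "net", "gcn", "head",
                     "drop", "gconv", "bn", "flatten"):
            if hasattr(obj, attr):
                walk(getattr(obj, attr))

    walk(root)
    return found


def get_state(params: list[Param], batchnorms: list[BatchNorm] = ()) -> dict:
    """Snapshot of parameter values and BN running moments."""
    return {
        "params": [p.value.copy() for p in params],
        "bn": [(bn.running_mean.copy(), bn.running_var.copy()) for bn in batchnorms],
    }


def set_state(params: list[Param], state: dict,
              batchnorms: list[BatchNorm] = ()) -> None:
    for p, s in zip(params, state["params"], strict=True):
        p.value[...] = s
    for bn, (mean, var) in zip(batchnorms, state["bn"], strict=True):
        bn.running_mean = mean.copy()
        bn.running_var = var.copy()
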