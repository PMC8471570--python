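"""Minimal 3D convolutional network with reverse-mode gradients on numpy.

Implements exactly the layer vocabulary the property-prediction network
needs — 3D convolution (stride 1, same padding), 3D max pooling, batch
normalization, dropout, dense layers, ReLU / leaky-ReLU — together with
mean-squared-error loss and an Adam optimizer.  Everything is float32,
seeded, and deterministic for a given seed.

Data layout is ``(batch, x, y, z, channels)``.  Convolution is computed
as a sum of 27 shifted matrix products (one per kernel offset), which
keeps memory linear in the activation size and vectorizes well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .errors import ShapeError

_F32 = np.float32


class Layer:
    """Base layer: ``params`` is a list of [value, grad] pairs."""

    def __init__(self):
        self.params: List[list] = []

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def out_shape(self, in_shape):
        return in_shape


class Conv3D(Layer):
    """3x3x3 (configurable, odd) convolution, stride 1, zero same-padding."""

    def __init__(self, c_in, c_out, kernel=3, rng=None):
        super().__init__()
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel**3 * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel, kernel, kernel, c_in, c_out))
        self.w = [w.astype(_F32), np.zeros_like(w, dtype=_F32)]
        self.b = [np.zeros(c_out, dtype=_F32), np.zeros(c_out, dtype=_F32)]
        self.params = [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        k, p = self.k, self.k // 2
        B, X, Y, Z, C = x.shape
        xp = np.zeros((B, X + 2 * p, Y + 2 * p, Z + 2 * p, C), dtype=_F32)
        xp[:, p:p + X, p:p + Y, p:p + Z] = x
        self._xp_shape = xp.shape
        self._xp = xp
        out = np.empty((B, X, Y, Z, self.c_out), dtype=_F32)
        out[:] = self.b[0]
        W = self.w[0]
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    sub = xp[:, a:a + X, b:b + Y, c:c + Z, :]
                    out += sub.reshape(-1, C).dot(W[a, b, c]).reshape(B, X, Y, Z, -1)
        return out

    def backward(self, dy):
        k = self.k
        B, X, Y, Z, F = dy.shape
        C = self.c_in
        xp = self._xp
        dxp = np.zeros_like(xp)
        W = self.w[0]
        dW = self.w[1]
        dW[...] = 0.0
        self.b[1][...] = dy.sum(axis=(0, 1, 2, 3))
        dyf = dy.reshape(-1, F)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    sub = xp[:, a:a + X, b:b + Y, c:c + Z, :].reshape(-1, C)
                    dW[a, b, c] = sub.T.dot(dyf)
                    dxp[:, a:a + X, b:b + Y, c:c + Z, :] += (
                        dyf.dot(W[a, b, c].T).reshape(B, X, Y, Z, C))
        p = k // 2
        self._xp = None
        return dxp[:, p:p + X, p:p + Y, p:p + Z, :]

    def out_shape(self, s):
        return (*s[:3], self.c_out)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(_F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(_F32)


class LeakyReLU(Layer):
    def __init__(self, alpha=0.3):
        super().__init__()
        self.alpha = _F32(alpha)

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x).astype(_F32)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy).astype(_F32)


class MaxPool3D(Layer):
    def __init__(self, pool: Tuple[int, int, int]):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False, rng=None):
        px, py, pz = self.pool
        B, X, Y, Z, C = x.shape
        if X % px or Y % py or Z % pz:
            raise ShapeError(f"input {x.shape[1:4]} not divisible by pool {self.pool}")
        xw = x.reshape(B, X // px, px, Y // py, py, Z // pz, pz, C)
        xw = xw.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
            B, X // px, Y // py, Z // pz, C, px * py * pz)
        self._arg = xw.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xw, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        px, py, pz = self.pool
        B, X, Y, Z, C = self._in_shape
        dxw = np.zeros((B, X // px, Y // py, Z // pz, C, px * py * pz), dtype=_F32)
        np.put_along_axis(dxw, self._arg[..., None], dy[..., None], axis=-1)
        dx = dxw.reshape(B, X // px, Y // py, Z // pz, C, px, py, pz)
        dx = dx.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(B, X, Y, Z, C)
        return dx

    def out_shape(self, s):
        px, py, pz = self.pool
        if s[0] % px or s[1] % py or s[2] % pz:
            raise ShapeError(f"shape {s[:3]} not divisible by pool {self.pool}")
        return (s[0] // px, s[1] // py, s[2] // pz, s[3])


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = [np.ones(channels, dtype=_F32), np.zeros(channels, dtype=_F32)]
        self.beta = [np.zeros(channels, dtype=_F32), np.zeros(channels, dtype=_F32)]
        self.params = [self.gamma, self.beta]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(_F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(_F32), training, axes,
                       np.prod([x.shape[a] for a in axes]))
        return (self.gamma[0] * xhat + self.beta[0]).astype(_F32)

    def backward(self, dy):
        xhat, inv, training, axes, n = self._cache
        self.gamma[1][...] = (dy * xhat).sum(axis=axes)
        self.beta[1][...] = dy.sum(axis=axes)
        if not training:
            return (dy * self.gamma[0] * inv).astype(_F32)
        g = dy * self.gamma[0]
        dx = (g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes)) * inv
        return dx.astype(_F32)


class Dropout(Layer):
    def __init__(self, rate):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_F32) / _F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def out_shape(self, s):
        return (int(np.prod(s)),)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        self.n_in = n_in
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w = [w.astype(_F32), np.zeros_like(w, dtype=_F32)]
        self.b = [np.zeros(n_out, dtype=_F32), np.zeros(n_out, dtype=_F32)]
        self.params = [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.n_in:
            raise ShapeError(f"dense layer expects {self.n_in} features, got {x.shape[1]}")
        self._x = x
        return x.dot(self.w[0]) + self.b[0]

    def backward(self, dy):
        self.w[1][...] = self._x.T.dot(dy)
        self.b[1][...] = dy.sum(axis=0)
        self._x = None
        return dy.dot(self.w[0].T)

    def out_shape(self, s):
        return (self.w[0].shape[1],)


# ---------------------------------------------------------------------------
# network container


@dataclass
class CNNConfig:
    """Architecture hyper-parameters of the property-prediction network.

    The defaults reproduce the bottleneck reference architecture: three
    conv/pool/batch-norm/dropout blocks with 16, 32 and 64 filters of
    3x3x3, pooling 2x2x2 except the last block which pools 2x2x1 so the
    20-slice depth (20 -> 10 -> 5) keeps a positive dimension, then
    dense layers of 32, 64 and 3 units with leaky-ReLU activations
    (linear output head).
    """

    input_shape: Tuple[int, int, int] = (32, 32, 20)
    conv_filters: Tuple[int, ...] = (16, 32, 64)
    kernel: int = 3
    pools: Tuple[Tuple[int, int, int], ...] = ((2, 2, 2), (2, 2, 2), (2, 2, 1))
    dropout_rate: float = 0.3
    dense_units: Tuple[int, ...] = (32, 64, 3)
    leaky_slope: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.dense_units[-1] != 3:
            raise ValueError("output head must have exactly 3 units")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


class Network:
    """Sequential layer stack with shared forward/backward plumbing."""

    def __init__(self, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: List[Layer] = []
        shape = (*config.input_shape, 1)
        c_in = 1
        for filt, pool in zip(config.conv_filters, config.pools):
            layers.append(Conv3D(c_in, filt, config.kernel, rng=rng))
            layers.append(ReLU())
            layers.append(MaxPool3D(pool))
            layers.append(BatchNorm(filt))
            layers.append(Dropout(config.dropout_rate))
            c_in = filt
        layers.append(Flatten())
        # walking the shapes validates pool divisibility at build time
        for lay in layers:
            shape = lay.out_shape(shape)
        n_in = shape[0]
        for i, units in enumerate(config.dense_units):
            layers.append(Dense(n_in, units, rng=rng))
            if i < len(config.dense_units) - 1:
                layers.append(LeakyReLU(config.leaky_slope))
            n_in = units
        self.layers = layers
        self.layer_shapes = self._shape_walk()

    def _shape_walk(self):
        shape = (*self.config.input_shape, 1)
        shapes = [shape]
        for lay in self.layers:
            shape = lay.out_shape(shape)
            shapes.append(shape)
        return shapes

    def forward(self, x, training=False, rng=None):
        if x.shape[1:4] != tuple(self.config.input_shape):
            raise ShapeError(
                f"input shape {x.shape[1:4]} does not match the configured "
                f"{tuple(self.config.input_shape)}")
        h = np.asarray(x, dtype=_F32).reshape(*x.shape[:4], 1)
        for lay in self.layers:
            h = lay.forward(h, training=training, rng=rng)
        return h

    def backward(self, dy):
        g = dy.astype(_F32)
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def parameters(self):
        return [p for lay in self.layers for p in lay.params]

    def get_weights(self):
        ws = [p[0].copy() for p in self.parameters()]
        for lay in self.layers:
            if isinstance(lay, BatchNorm):
                ws.append(lay.running_mean.copy())
                ws.append(lay.running_var.copy())
        return ws

    def set_weights(self, ws):
        ws = list(ws)
        params = self.parameters()
        for p, w in zip(params, ws[:len(params)]):
            p[0][...] = w
        i = len(params)
        for lay in self.layers:
            if isinstance(lay, BatchNorm):
                lay.running_mean[...] = ws[i]
                lay.running_var[...] = ws[i + 1]
                i += 2

    @property
    def n_parameters(self):
        return int(sum(p[0].size for p in self.parameters()))


class Adam:
    """Adam optimizer over a network's [value, grad] parameter pairs."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p[0]) for p in params]
        self.v = [np.zeros_like(p[0]) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p[1]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p[0] -= (self.lr * (m / b1t)
                     / (np.sqrt(v / b2t) + self.eps)).astype(p[0].dtype)


def mse_loss(pred, target):
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = (pred - target).astype(_F32)
    loss = float(np.mean(diff**2))
    grad = (2.0 / diff.size) * diff
    return loss, grad
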