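"""Vectorised NumPy layers with forward/backward passes.

Tensors are channels-last: images are ``(N, H, W, C)`` float32, dense
activations ``(N, F)``.  Each layer owns its parameters and, after a
backward pass, the matching gradients; the Adam optimiser in
:mod:`btcnn.netcore.network` updates them in place.  Convolutions use
im2col (``sliding_window_view`` + matmul), their gradients scatter-add
over the 3x3 taps.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2DSame",
    "DepthwiseConv2DSame",
    "PointwiseConv",
    "ReLU",
    "BatchNorm",
    "AvgPool",
    "Dense",
    "Dropout",
    "Flatten",
]

DTYPE = np.float32


def glorot_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, sd, size=shape).astype(DTYPE)


class Layer:
    """Base layer: parameter-free and stateless unless overridden."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def param_count(self) -> tuple[int, int]:
        """(trainable, non_trainable) parameters of this layer."""
        return sum(p.size for p in self.params.values()), 0


def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    top, left = (kh - 1) // 2, (kw - 1) // 2
    return np.pad(x, ((0, 0), (top, kh - 1 - top), (left, kw - 1 - left), (0, 0)))


class Conv2DSame(Layer):
    """3x3 (or kh x kw) convolution, stride 1, 'same' padding, with bias."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator) -> None:
        super().__init__()
        kh, kw = kernel
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        fan_in, fan_out = kh * kw * c_in, kh * kw * c_out
        self.params = {
            "w": glorot_normal(rng, (kh * kw * c_in, c_out), fan_in, fan_out),
            "b": np.zeros(c_out, dtype=DTYPE),
        }

    def forward(self, x, training):
        n, h, w, _ = x.shape
        xp = _pad_same(x, self.kh, self.kw)
        cols = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        # (N, H, W, C, kh, kw) -> (N*H*W, kh*kw*C) matching weight layout
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        self._cols = cols.reshape(n * h * w, -1)
        self._in_shape = x.shape
        out = self._cols @ self.params["w"] + self.params["b"]
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout):
        n, h, w, _ = self._in_shape
        dflat = dout.reshape(n * h * w, self.c_out)
        self.grads["w"] = self._cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["w"].T).reshape(
            n, h, w, self.kh, self.kw, self.c_in
        )
        top, left = (self.kh - 1) // 2, (self.kw - 1) // 2
        dxp = np.zeros(
            (n, h + self.kh - 1, w + self.kw - 1, self.c_in), dtype=dout.dtype
        )
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, top:top + h, left:left + w, :]


class DepthwiseConv2DSame(Layer):
    """Per-channel 3x3 convolution, stride 1, 'same' padding, with bias."""

    def __init__(self, c_in: int, kernel: tuple[int, int],
                 rng: np.random.Generator) -> None:
        super().__init__()
        kh, kw = kernel
        self.kh, self.kw, self.c_in = kh, kw, c_in
        self.params = {
            "w": glorot_normal(rng, (kh, kw, c_in), kh * kw, kh * kw),
            "b": np.zeros(c_in, dtype=DTYPE),
        }

    def forward(self, x, training):
        xp = _pad_same(x, self.kh, self.kw)
        # (N, H, W, C, kh, kw)
        self._windows = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        w = self.params["w"].transpose(2, 0, 1)  # (C, kh, kw)
        out = np.einsum("nhwcij,cij->nhwc", self._windows, w, optimize=True)
        self._in_shape = x.shape
        return out + self.params["b"]

    def backward(self, dout):
        n, h, w, c = self._in_shape
        dw = np.einsum("nhwcij,nhwc->cij", self._windows, dout, optimize=True)
        self.grads["w"] = dw.transpose(1, 2, 0)
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        top, left = (self.kh - 1) // 2, (self.kw - 1) // 2
        dxp = np.zeros((n, h + self.kh - 1, w + self.kw - 1, c), dtype=dout.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + h, j:j + w, :] += self.params["w"][i, j] * dout
        return dxp[:, top:top + h, left:left + w, :]


class PointwiseConv(Layer):
    """1x1 convolution: a dense map over the channel axis, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "w": glorot_normal(rng, (c_in, c_out), c_in, c_out),
            "b": np.zeros(c_out, dtype=DTYPE),
        }

    def forward(self, x, training):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = np.tensordot(self._x, dout, axes=([0, 1, 2], [0, 1, 2]))
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        return dout @ self.params["w"].T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalisation over the (N, H, W) axes.

    Training uses the biased mini-batch statistics; inference uses
    exponentially-smoothed moving statistics, which are the layer's
    non-trainable parameters.
    """

    def __init__(self, channels: int, epsilon: float = 1e-3,
                 momentum: float = 0.9) -> None:
        super().__init__()
        self.channels = channels
        self.epsilon = epsilon
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=DTYPE),
            "beta": np.zeros(channels, dtype=DTYPE),
        }
        self.moving_mean = np.zeros(channels, dtype=DTYPE)
        self.moving_var = np.ones(channels, dtype=DTYPE)

    def param_count(self):
        return 2 * self.channels, 2 * self.channels

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean = (
                self.momentum * self.moving_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.moving_var = (
                self.momentum * self.moving_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.moving_mean, self.moving_var
        self._inv_std = 1.0 / np.sqrt(var + self.epsilon)
        self._xhat = (x - mean) * self._inv_std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._axes = axes
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes = self._axes
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"] * self._inv_std
        return g * (
            dout
            - dout.mean(axis=axes)
            - self._xhat * (dout * self._xhat).mean(axis=axes)
        )


class AvgPool(Layer):
    """Average pooling with window == stride (the published 2x2/2 case).

    Odd trailing rows/columns are dropped, so output size floors."""

    def __init__(self, window: tuple[int, int] = (2, 2)) -> None:
        super().__init__()
        self.window = window

    def forward(self, x, training):
        n, h, w, c = x.shape
        wh, ww = self.window
        if h < wh or w < ww:
            raise ValueError("pool window larger than the feature map")
        ho, wo = h // wh, w // ww
        self._in_shape = x.shape
        xc = x[:, : ho * wh, : wo * ww, :]
        return xc.reshape(n, ho, wh, wo, ww, c).mean(axis=(2, 4))

    def backward(self, dout):
        n, h, w, c = self._in_shape
        wh, ww = self.window
        ho, wo = h // wh, w // ww
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        spread = np.broadcast_to(
            dout[:, :, None, :, None, :] / (wh * ww), (n, ho, wh, wo, ww, c)
        )
        dx[:, : ho * wh, : wo * ww, :] = spread.reshape(n, ho * wh, wo * ww, c)
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "w": glorot_normal(rng, (n_in, n_out), n_in, n_out),
            "b": np.zeros(n_out, dtype=DTYPE),
        }

    def forward(self, x, training):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class Dropout(Layer):
    """Inverted dropout; active only while training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)
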