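"""Small reference implementations of the layer math.

These exist so the numerical building blocks of the network can be unit
tested against hand-computed values and brute-force oracles, independent
of the vectorised training backend in :mod:`btcnn.netcore.layers`.
Convolution is cross-correlation, F(i,j) = sum_m sum_n I(i+m, j+n) K(m,n),
as is standard for CNNs (no kernel flip).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Kernel2D",
    "BatchNormState",
    "PoolSpec",
    "convolve2d",
    "batch_norm",
    "pool2d",
    "softmax",
    "softmax_cross_entropy",
]

PROB_CLIP = 1e-12  # lower clip inside cross-entropy; log(0) is undefined


@dataclass(frozen=True)
class Kernel2D:
    weights: np.ndarray  # (m, n)
    bias: float = 0.0


@dataclass(frozen=True)
class BatchNormState:
    gamma: float = 1.0
    beta: float = 0.0
    epsilon: float = 1e-3


@dataclass(frozen=True)
class PoolSpec:
    window: tuple[int, int] = (2, 2)
    stride: tuple[int, int] = (2, 2)
    mode: str = "avg"  # "avg" or "max"


def convolve2d(image: np.ndarray, kernel: Kernel2D, padding: str = "valid") -> np.ndarray:
    """2-D cross-correlation of a single-channel image with one kernel.

    ``padding='same'`` zero-pads so the output matches the input size;
    ``'valid'`` returns the (H-m+1, W-n+1) map.
    """
    image = np.asarray(image, dtype=float)
    w = np.asarray(kernel.weights, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if w.ndim != 2 or w.size == 0:
        raise ValueError("kernel must be a non-empty 2-D array")
    m, n = w.shape
    if padding == "same":
        top, left = (m - 1) // 2, (n - 1) // 2
        image = np.pad(image, ((top, m - 1 - top), (left, n - 1 - left)))
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    if image.shape[0] < m or image.shape[1] < n:
        raise ValueError("kernel does not fit within the image")
    windows = sliding_window_view(image, (m, n))
    return np.tensordot(windows, w, axes=([2, 3], [0, 1])) + kernel.bias


def batch_norm(batch, state: BatchNormState) -> np.ndarray:
    """Mini-batch normalisation with the biased (divide-by-m) variance.

    t_hat = (t - mu_B) / sqrt(sigma2_B + eps); output = beta + gamma * t_hat.
    """
    t = np.asarray(batch, dtype=float)
    if t.size == 0:
        raise ValueError("batch must be non-empty")
    mu = t.mean()
    var = ((t - mu) ** 2).mean()
    t_hat = (t - mu) / np.sqrt(var + state.epsilon)
    return state.beta + state.gamma * t_hat


def pool2d(feature_map: np.ndarray, spec: PoolSpec) -> np.ndarray:
    """Windowed pooling; output size = floor((in - window)/stride) + 1."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 2:
        raise ValueError("feature map must be 2-D")
    (wh, ww), (sh, sw) = spec.window, spec.stride
    if fm.shape[0] < wh or fm.shape[1] < ww:
        raise ValueError("pool window larger than the feature map")
    windows = sliding_window_view(fm, (wh, ww))[::sh, ::sw]
    if spec.mode == "avg":
        return windows.mean(axis=(2, 3))
    if spec.mode == "max":
        return windows.max(axis=(2, 3))
    raise ValueError(f"unknown pool mode {spec.mode!r}")


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(truth, predicted) -> float:
    """Categorical cross-entropy, CE = -sum_i t_i log s_i.

    ``truth`` must be one-hot and ``predicted`` a probability vector;
    probabilities are clipped to [1e-12, 1] before the log.
    """
    t = np.asarray(truth, dtype=float)
    s = np.asarray(predicted, dtype=float)
    if t.shape != s.shape:
        raise ValueError("truth and prediction shapes differ")
    if np.any(s < 0):
        raise ValueError("negative probabilities")
    if not np.isclose(s.sum(), 1.0, atol=1e-5):
        raise ValueError("predicted probabilities must sum to 1")
    if not (np.isclose(t.sum(), 1.0) and np.all((t == 0) | (t == 1))):
        raise ValueError("truth must be one-hot")
    return float(-(t * np.log(np.clip(s, PROB_CLIP, 1.0))).sum())
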