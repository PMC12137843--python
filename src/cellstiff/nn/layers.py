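"""Minimal trainable layers for compact CNNs.

All layers operate on channels-last float64 arrays: images are
``(N, H, W, C)``, flat features ``(N, D)``. Each layer caches what its
backward pass needs during :meth:`forward`; :meth:`backward` consumes the
cache and accumulates parameter gradients in-place (``dW``, ``db``), so a
layer instance is not re-entrant across interleaved forward passes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def params(self):
        """Return list of (array, grad) pairs updated by the optimizer."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, zero 'same' padding, via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * in_channels
        # He initialization for ReLU nets
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(kernel, kernel, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _wmat(self):
        k, c, f = self.kernel, self.in_channels, self.out_channels
        # cols are ordered (C, kh, kw); match by transposing W
        return self.W.transpose(2, 0, 1, 3).reshape(c * k * k, f)

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ValueError(
                f"Conv2D expects (N,H,W,{self.in_channels}), got {x.shape}")
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
        n, h, w = win.shape[:3]
        cols = win.reshape(n, h, w, self.in_channels * k * k)
        out = cols @ self._wmat() + self.b
        if train:
            self._cache = (cols, x.shape)
        return out

    def backward(self, grad):
        cols, xshape = self._cache
        n, h, w, _ = grad.shape
        k, c, f = self.kernel, self.in_channels, self.out_channels
        gmat = grad.reshape(-1, f)
        self.dW += (cols.reshape(-1, c * k * k).T @ gmat).reshape(
            c, k, k, f).transpose(1, 2, 0, 3)
        self.db += gmat.sum(axis=0)
        gcols = (grad @ self._wmat().T).reshape(n, h, w, c, k, k)
        p = k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += gcols[:, :, :, :, i, j]
        return dxp[:, p:p + xshape[1], p:p + xshape[2], :]


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=True):
        s = self.size
        n, h, w, c = x.shape
        ho, wo = h // s, w // s
        xc = x[:, :ho * s, :wo * s, :]
        xr = xc.reshape(n, ho, s, wo, s, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, ho, wo, c, s * s)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, grad):
        idx, xshape = self._cache
        s = self.size
        n, h, w, c = xshape
        ho, wo = h // s, w // s
        gr = np.zeros((n, ho, wo, c, s * s))
        np.put_along_axis(gr, idx[..., None], grad[..., None], axis=-1)
        gr = gr.reshape(n, ho, wo, c, s, s).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(xshape)
        dx[:, :ho * s, :wo * s, :] = gr.reshape(n, ho * s, wo * s, c)
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features),
                            size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        if x.ndim != 2 or x.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"Dense expects (N,{self.W.shape[0]}), got {x.shape}")
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T
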