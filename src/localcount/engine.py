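"""Minimal NumPy neural-network engine (NCHW, float32).

Implements exactly the layer set the counting networks need — strided padded
convolution, 2x2 max pooling, batch normalization, ReLU — with reverse-mode
gradients, so models declared as :class:`localcount.arch.NetworkSpec` can be
trained with plain SGD. Convolutions run as im2col + a single BLAS GEMM;
col2im scatters gradients with one vectorized add per kernel offset, so there
are no Python loops over pixels anywhere.

Weight initialization is the He/"improved Xavier" scheme,
``W ~ N(0, sqrt(2 / fan_in))``, appropriate for ReLU stacks.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import GeometryError

__all__ = ["Conv2d", "MaxPool2d", "BatchNorm2d", "ReLU", "Sequential", "SGD"]


class Layer:
    """Base layer: forward caches whatever backward needs."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> Dict[str, np.ndarray]:
        return {}

    def gradients(self) -> Dict[str, np.ndarray]:
        return {}

    def buffers(self) -> Dict[str, np.ndarray]:
        return {}


class Conv2d(Layer):
    def __init__(self, in_channels: int, out_channels: int,
                 kernel: Tuple[int, int], stride: int = 1, padding: int = 0,
                 rng: Optional[np.random.Generator] = None):
        kh, kw = kernel
        self.cin, self.cout = in_channels, out_channels
        self.kh, self.kw = kh, kw
        self.stride, self.padding = stride, padding
        fan_in = kh * kw * in_channels
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels, kh, kw)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def out_hw(self, h: int, w: int) -> Tuple[int, int]:
        ho = (h + 2 * self.padding - self.kh) // self.stride + 1
        wo = (w + 2 * self.padding - self.kw) // self.stride + 1
        if ho < 1 or wo < 1:
            raise GeometryError(
                f"conv {self.kh}x{self.kw}/{self.stride}: input {h}x{w} too small")
        return ho, wo

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = self.out_hw(h, w)
        p, s = self.padding, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # (N, C, Ho, Wo, kh, kw) view, then one GEMM
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))[:, :, ::s, ::s]
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, self.cin * self.kh * self.kw)
        wf = self.W.reshape(self.cout, -1)
        y = col @ wf.T
        y += self.b
        if training:
            self._cache = (col, (n, c, h, w))
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, (n, c, h, w) = self._cache
        _, cout, ho, wo = dy.shape
        p, s = self.padding, self.stride
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.dW[...] = (dyf.T @ col).reshape(self.W.shape)
        self.db[...] = dyf.sum(axis=0)
        dcol = (dyf @ self.W.reshape(cout, -1)).reshape(
            n, ho, wo, self.cin, self.kh, self.kw)
        dcol = dcol.transpose(0, 3, 4, 5, 1, 2)  # (N, C, kh, kw, Ho, Wo)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcol[:, :, i, j]
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def parameters(self) -> Dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def gradients(self) -> Dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel == stride), the AlexNet-like 2x2/2."""

    def __init__(self, kernel: int = 2, stride: int = 2):
        if kernel != stride:
            raise GeometryError("MaxPool2d supports kernel == stride only")
        self.k = kernel
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        ho, wo = h // k, w // k
        if ho < 1 or wo < 1:
            raise GeometryError(f"maxpool {k}x{k}: input {h}x{w} too small")
        xv = x[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
        xv = np.ascontiguousarray(xv.transpose(0, 1, 2, 4, 3, 5)).reshape(
            n, c, ho, wo, k * k)
        idx = xv.argmax(axis=-1)
        y = np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, (n, c, h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        k = self.k
        ho, wo = dy.shape[2], dy.shape[3]
        dxv = np.zeros((n, c, ho, wo, k * k), dtype=np.float32)
        np.put_along_axis(dxv, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, :ho * k, :wo * k] = dxv.reshape(n, c, ho, wo, k, k).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, ho * k, wo * k)
        self._cache = None
        return dx


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.c = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        if training:
            self._cache = (xhat.astype(np.float32), inv_std.astype(np.float32))
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g = (self.gamma * inv_std / m)[None, :, None, None]
        dx = g * (m * dy
                  - self.dbeta[None, :, None, None]
                  - xhat * self.dgamma[None, :, None, None])
        self._cache = None
        return dx.astype(np.float32)

    def parameters(self) -> Dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    def gradients(self) -> Dict[str, np.ndarray]:
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def buffers(self) -> Dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
            return np.where(self._mask, x, np.float32(0.0))
        return np.maximum(x, 0, out=x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, np.float32(0.0))
        self._mask = None
        return dx


class Sequential:
    def __init__(self, layers: List[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_arrays(self) -> Dict[str, np.ndarray]:
        """Flat name -> array map of every parameter and buffer (live views)."""
        out: Dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in {**layer.parameters(), **layer.buffers()}.items():
                out[f"layer{i:02d}.{k}"] = v
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_arrays().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        arrays = self.named_arrays()
        missing = set(arrays) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in arrays.items():
            v[...] = state[k]


class SGD:
    """Plain stochastic gradient descent (no momentum, no weight decay)."""

    def __init__(self, net: Sequential, lr: float):
        self.net = net
        self.lr = lr

    def step(self) -> None:
        for layer in self.net.layers:
            params, grads = layer.parameters(), layer.gradients()
            for k in params:
                params[k] -= self.lr * grads[k]
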