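"""Minimal dense-prediction layer library (numpy, channels-last).

Implements exactly the operations the residual U-Net needs — 2-D
convolution ('same' padding, stride 1 or 2), batch normalization, ReLU,
sigmoid and 2x nearest-neighbour upsampling — each with an explicit
backward pass. Layout is ``(N, H, W, C)`` float32. Forward passes cache
intermediates only when ``train=True``, so inference on the full-size
networks stays memory-light.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) array pairs; gradients filled by backward."""
        return []


def _same_pads(size: int, k: int, stride: int) -> tuple[int, int, int]:
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k - size, 0)
    lo = total // 2
    return out, lo, total - lo


class Conv2D(Layer):
    """k x k convolution, TF-style 'same' padding, stride 1 or 2."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * k * cin))  # He init for ReLU stacks
        self.W = rng.normal(0.0, scale, size=(k, k, cin, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride = k, stride
        self._cache = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        k, s = self.k, self.stride
        n, _, _, c = xp.shape
        cols = np.empty((n, oh, ow, k * k * c), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[..., (i * k + j) * c : (i * k + j + 1) * c] = xp[
                    :, i : i + s * (oh - 1) + 1 : s, j : j + s * (ow - 1) + 1 : s, :
                ]
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, cin = x.shape
        k, s = self.k, self.stride
        oh, pt, pb = _same_pads(h, k, s)
        ow, pl, pr = _same_pads(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = self._im2col(xp, oh, ow)
        cout = self.W.shape[-1]
        out = cols.reshape(-1, k * k * cin) @ self.W.reshape(-1, cout) + self.b
        out = out.reshape(n, oh, ow, cout)
        if train:
            self._cache = (cols, xp.shape, (pt, pl), (h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, (pt, pl), (h, w) = self._cache
        k, s = self.k, self.stride
        n, oh, ow, cout = dout.shape
        cin = self.W.shape[2]
        g = dout.reshape(-1, cout)
        self.dW[...] = (cols.reshape(-1, k * k * cin).T @ g).reshape(self.W.shape)
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.reshape(-1, cout).T).reshape(n, oh, ow, k * k * cin)
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * (oh - 1) + 1 : s, j : j + s * (ow - 1) + 1 : s, :] += dcols[
                    ..., (i * k + j) * cin : (i * k + j + 1) * cin
                ]
        self._cache = None
        return dxp[:, pt : pt + h, pl : pl + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        if train:
            self._cache = (xhat, ivar)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        self._cache = None
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 1, 2))
        self.dbeta[...] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma
        return (ivar / m) * (
            m * dxhat - dxhat.sum(axis=(0, 1, 2)) - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout * self._mask
        self._mask = None
        return out


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        if train:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout * self._out * (1.0 - self._out)
        self._out = None
        return out


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dout.shape
        return dout.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
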