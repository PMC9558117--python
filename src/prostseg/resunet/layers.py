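"""Minimal CPU layer zoo with explicit forward/backward passes.

Tensors are ``(n, c, h, w)`` float arrays.  Each layer caches what its
backward pass needs during ``forward`` and accumulates parameter gradients
in ``backward``; ``params()`` exposes parameter/gradient pairs for the
optimizer.  float64 is supported throughout so gradients can be verified by
finite differences.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid", "MaxPool2d", "UpsampleNearest2d"]


class Layer:
    name: str = "layer"

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p["grad"][...] = 0.0


class Conv2d(Layer):
    """Stride-1 convolution with 'same' zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("only odd kernels supported")
        self.name = name
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.kernel, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (n, c, h, w, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        self._cols = cols if train else None
        self._xshape = (n, c, h, w)
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wmat.T + self.b
        return np.ascontiguousarray(out.reshape(n, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cols is None:
            raise RuntimeError("backward before forward(train=True)")
        n, c, h, w = self._xshape
        k, p = self.kernel, self.pad
        out_ch = self.w.shape[0]
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * h * w, out_ch)
        self.dw += (g2.T @ self._cols).reshape(self.w.shape)
        self.db += g2.sum(axis=0)
        dcols = (g2 @ self.w.reshape(out_ch, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def params(self) -> list[dict]:
        return [
            {"name": f"{self.name}.w", "value": self.w, "grad": self.dw},
            {"name": f"{self.name}.b", "value": self.b, "grad": self.db},
        ]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class BatchNorm2d(Layer):
    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5, name: str = "bn"):
        self.name = name
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, train, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.dgamma += (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma[None, :, None, None]
        if not train:
            return dxhat * invstd[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)

    def params(self) -> list[dict]:
        return [
            {"name": f"{self.name}.gamma", "value": self.gamma, "grad": self.dgamma},
            {"name": f"{self.name}.beta", "value": self.beta, "grad": self.dbeta},
        ]

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        from scipy.special import expit

        self._out = expit(x)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {(h, w)} not divisible by 2")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = blocks.argmax(axis=-1)
        self._inshape = x.shape
        return blocks.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._argmax[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class UpsampleNearest2d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
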