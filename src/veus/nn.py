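"""Minimal convolutional network layers with explicit backpropagation.

A small, self-contained layer library (conv / transposed conv via im2col,
batch normalization, ReLU family, Tanh, nearest-neighbor resize, Adam) that
the translation model is built on.  Layers follow a forward/backward
protocol: ``forward`` caches what the gradient needs, ``backward`` takes the
upstream gradient, optionally accumulates parameter gradients, and returns
the gradient with respect to the input.  All arrays are float64
(N, C, H, W).

The implementation favours clarity and exactness over speed; convolutions
reduce to BLAS matmuls through im2col/col2im, which is fast enough for the
desk-scale experiments this package runs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
    "ReLU", "LeakyReLU", "Tanh", "NearestResize", "Adam",
    "sigmoid", "softplus", "bce_logits", "bce_logits_grad",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


# ---------------------------------------------------------------------------
# im2col / col2im

def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, C*k*k, Hout*Wout) patch matrix."""
    n, c, h, w = x.shape
    hout = (h + 2 * pad - k) // stride + 1
    wout = (w + 2 * pad - k) // stride + 1
    xp = _pad(x, pad)
    view = sliding_window_view(xp, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride][:, :, :hout, :wout]
    cols = np.ascontiguousarray(view.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(n, c * k * k, hout * wout), hout, wout


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int,
           hout: int, wout: int) -> np.ndarray:
    """Scatter-add inverse of im2col back onto an (N, C, H, W) canvas."""
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, c, k, k, hout, wout)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * hout:stride,
               j:j + stride * wout:stride] += cols[:, :, i, j]
    if pad == 0:
        return xp
    return xp[:, :, pad:pad + h, pad:pad + w]


# ---------------------------------------------------------------------------
# layers

class Conv2d:
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.weight = Param(rng.normal(0.0, init_std, size=(cout, cin * k * k)))
        self.bias = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        cols, hout, wout = im2col(x, self.k, self.stride, self.pad)
        out = np.matmul(self.weight.data, cols) + self.bias.data[:, None]
        self._cache = (cols, x.shape, hout, wout)
        return out.reshape(x.shape[0], self.cout, hout, wout)

    def backward(self, dout: np.ndarray, update_params: bool = True) -> np.ndarray:
        cols, x_shape, hout, wout = self._cache
        df = dout.reshape(dout.shape[0], self.cout, -1)
        if update_params:
            self.weight.grad += np.tensordot(df, cols, axes=([0, 2], [0, 2]))
            self.bias.grad += df.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.data.T, df)
        return col2im(dcols, x_shape, self.k, self.stride, self.pad, hout, wout)


class ConvTranspose2d:
    """Fractionally-strided convolution (the exact adjoint of Conv2d)."""

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.weight = Param(rng.normal(0.0, init_std, size=(cin, cout * k * k)))
        self.bias = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        hout = (h - 1) * self.stride - 2 * self.pad + self.k
        wout = (w - 1) * self.stride - 2 * self.pad + self.k
        xf = x.reshape(n, c, h * w)
        cols = np.matmul(self.weight.data.T, xf)  # (N, cout*k*k, h*w)
        out = col2im(cols, (n, self.cout, hout, wout), self.k, self.stride,
                     self.pad, h, w)
        out += self.bias.data[None, :, None, None]
        self._cache = (xf, x.shape, (hout, wout))
        return out

    def backward(self, dout: np.ndarray, update_params: bool = True) -> np.ndarray:
        xf, x_shape, _ = self._cache
        n, c, h, w = x_shape
        dcols, _, _ = im2col(dout, self.k, self.stride, self.pad)  # (N, cout*k*k, h*w)
        if update_params:
            self.weight.grad += np.tensordot(xf, dcols, axes=([0, 2], [0, 2]))
            self.bias.grad += dout.sum(axis=(0, 2, 3))
        dxf = np.matmul(self.weight.data, dcols)
        return dxf.reshape(x_shape)


class BatchNorm2d:
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Param(rng.normal(1.0, init_std, size=c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout: np.ndarray, update_params: bool = True) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        if update_params:
            self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return dout * g * inv_std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * g
        # standard batch-norm backward through the batch statistics
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return term * inv_std[None, :, None, None]


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray, update_params: bool = True) -> np.ndarray:
        return dout * self._mask


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray, update_params: bool = True) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class Tanh:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout: np.ndarray, update_params: bool = True) -> np.ndarray:
        return dout * (1.0 - self._out ** 2)


class NearestResize:
    """Nearest-neighbor spatial resize with an exact scatter-add adjoint."""

    def __init__(self, out_h: int, out_w: int):
        self.out_h, self.out_w = out_h, out_w

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        self._ri = (np.arange(self.out_h) * h // self.out_h).astype(np.int64)
        self._ci = (np.arange(self.out_w) * w // self.out_w).astype(np.int64)
        return x[:, :, self._ri[:, None], self._ci[None, :]]

    def backward(self, dout: np.ndarray, update_params: bool = True) -> np.ndarray:
        dx = np.zeros(self._in_shape)
        np.add.at(dx, (slice(None), slice(None), self._ri[:, None], self._ci[None, :]), dout)
        return dx


# ---------------------------------------------------------------------------
# losses and optimizer

def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def bce_logits(label: float, logits: np.ndarray) -> float:
    """Mean binary cross-entropy of a constant label against a logit map."""
    return float(np.mean(softplus(-logits) + (1.0 - label) * logits))


def bce_logits_grad(label: float, logits: np.ndarray) -> np.ndarray:
    """d/dlogits of :func:`bce_logits` (already divided by the element count)."""
    return (sigmoid(logits) - label) / logits.size


class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
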