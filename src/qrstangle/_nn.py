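"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Internal support code for :mod:`qrstangle.model_loss`.  Sequence tensors are
``(batch, length, channels)``; dense tensors ``(batch, features)``.  Each
layer caches what its backward pass needs; ``backward`` must be called with
the same ``train`` mode that produced the cache.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Adam",
    "Conv1d",
    "Dense",
    "DepthwiseConv1d",
    "Dropout",
    "GlobalAvgPool1d",
    "LayerNorm",
    "LeakyReLU",
    "MaxPool1d",
    "Parameter",
]


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Full 1-D convolution, stride 1.  kernel_size 3 uses 'same' zero padding,
    kernel_size 1 none."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        self.k = kernel_size
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (kernel_size * c_in))
        self.w = Parameter(rng.normal(0.0, scale, size=(kernel_size * c_in, c_out)), "conv_w")
        self.b = Parameter(np.zeros(c_out), "conv_b")
        self.pad = (kernel_size - 1) // 2

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, _ = x.shape
        if self.pad:
            xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        else:
            xp = x
        # (n, L, k, c_in) -> (n*L, k*c_in)
        cols = sliding_window_view(xp, self.k, axis=1).transpose(0, 1, 3, 2)
        self._cols = cols.reshape(n * length, self.k * self.c_in)
        self._shape = (n, length)
        out = self._cols @ self.w.value + self.b.value
        return out.reshape(n, length, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length = self._shape
        dy2 = dy.reshape(n * length, self.c_out)
        self.w.grad += self._cols.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.w.value.T).reshape(n, length, self.k, self.c_in)
        dxp = np.zeros((n, length + 2 * self.pad, self.c_in))
        for k in range(self.k):
            dxp[:, k : k + length, :] += dcols[:, :, k, :]
        return dxp[:, self.pad : self.pad + length, :] if self.pad else dxp


class DepthwiseConv1d(Layer):
    """Per-lead convolution: each of ``j`` input channels gets ``f`` private
    kernels, producing ``j * f`` feature maps (lead-major order)."""

    def __init__(self, j: int, per_lead: int, kernel_size: int, rng: np.random.Generator):
        self.j, self.f, self.k = j, per_lead, kernel_size
        scale = np.sqrt(2.0 / kernel_size)
        self.w = Parameter(rng.normal(0.0, scale, size=(kernel_size, j, per_lead)), "dwconv_w")
        self.b = Parameter(np.zeros(j * per_lead), "dwconv_b")
        self.pad = (kernel_size - 1) // 2

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        wins = sliding_window_view(xp, self.k, axis=1)  # (n, L, j, k)
        self._wins = wins
        self._shape = (n, length)
        out = np.einsum("nljk,kjf->nljf", wins, self.w.value)
        return out.reshape(n, length, self.j * self.f) + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length = self._shape
        dy4 = dy.reshape(n, length, self.j, self.f)
        self.w.grad += np.einsum("nljk,nljf->kjf", self._wins, dy4)
        self.b.grad += dy.sum(axis=(0, 1))
        dxp = np.zeros((n, length + 2 * self.pad, self.j))
        contrib = np.einsum("nljf,kjf->nlkj", dy4, self.w.value)
        for k in range(self.k):
            dxp[:, k : k + length, :] += contrib[:, :, k, :]
        return dxp[:, self.pad : self.pad + length, :]


class LayerNorm(Layer):
    """Per-sample normalization with trainable per-feature-map scale and shift.

    Sequence tensors ``(batch, length, channels)`` have each feature map
    normalized over its time axis, so the isoelectric baseline stays near
    zero and localized waves keep their relative prominence through pooling.
    Dense tensors ``(batch, features)`` are normalized over the feature axis.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c), "ln_gamma")
        self.beta = Parameter(np.zeros(c), "ln_beta")
        self.eps = eps

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axis = 1 if x.ndim == 3 else -1
        mu = x.mean(axis=axis, keepdims=True)
        var = x.var(axis=axis, keepdims=True)
        self._axis = axis
        self._m = x.shape[axis]
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        axis, m = self._axis, self._m
        param_axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=param_axes)
        self.beta.grad += dy.sum(axis=param_axes)
        dxhat = dy * self.gamma.value
        return (
            inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axis, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=axis, keepdims=True)
            )
        )


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class MaxPool1d(Layer):
    """Pool 2, stride 2 along the length axis; an odd trailing sample is dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, c = x.shape
        out_len = length // self.pool
        self._in_len = length
        blocks = x[:, : out_len * self.pool, :].reshape(n, out_len, self.pool, c)
        self._argmax = blocks.argmax(axis=2)
        return blocks.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, out_len, c = dy.shape
        dblocks = np.zeros((n, out_len, self.pool, c))
        np.put_along_axis(dblocks, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, self._in_len, c))
        dx[:, : out_len * self.pool, :] = dblocks.reshape(n, out_len * self.pool, c)
        return dx


class GlobalAvgPool1d(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._length, axis=1) / self._length


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = self.rng.random(x.shape) >= self.p
        return x * self._mask / (1.0 - self.p)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask / (1.0 - self.p)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(c_in, c_out)), "dense_w")
        self.b = Parameter(np.zeros(c_out), "dense_b")

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Adam:
    """Adam with the conventional default moments (0.9, 0.999)."""

    def __init__(self, params: list[Parameter], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
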