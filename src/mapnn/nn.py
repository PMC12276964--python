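"""Minimal numpy neural-network engine used by the map estimator.

Implements exactly the layer types the two-branch architecture needs —
dense, 1-D convolution, average pooling, ReLU — with hand-written
backward passes and an Adam optimizer.  Gradients are verified against
finite differences in the test suite.  Weights initialize from a
Glorot-style uniform distribution; biases start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Param", "Dense", "Conv1D", "AvgPool1D", "relu", "Adam"]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self):
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape,
            dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Dense:
    """y = x @ W + b over the last axis, optional ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None, dtype=np.float64):
        self.W = Param(_glorot(rng, n_in, n_out, (n_in, n_out), dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))
        self.activation = activation
        self._x = None
        self._z = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "relu":
            self._z = z
            return relu(z)
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            g = g * (self._z > 0)
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return g @ self.W.value.T


class Conv1D:
    """Valid-mode 1-D convolution along axis 1 of (N, L, C_in), optional ReLU."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 activation: str | None = "relu", dtype=np.float64):
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.W = Param(_glorot(rng, kernel * c_in, c_out, (kernel * c_in, c_out), dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.activation = activation
        self._cols = None
        self._z = None
        self._in_len = None

    @property
    def params(self):
        return [self.W, self.b]

    def out_len(self, L: int) -> int:
        return L - self.kernel + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, L, C = x.shape
        self._in_len = L
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (N, Lout, C, k) -> columns (N, Lout, k*C)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            N, L - self.kernel + 1, self.kernel * C)
        self._cols = cols
        z = cols @ self.W.value + self.b.value
        if self.activation == "relu":
            self._z = z
            return relu(z)
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            g = g * (self._z > 0)
        N, Lout, _ = g.shape
        cols2 = self._cols.reshape(-1, self.kernel * self.c_in)
        g2 = g.reshape(-1, self.c_out)
        self.W.grad += cols2.T @ g2
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value.T).reshape(N, Lout, self.kernel, self.c_in)
        dx = np.zeros((N, self._in_len, self.c_in), dtype=g.dtype)
        for i in range(self.kernel):
            dx[:, i:i + Lout, :] += dcols[:, :, i, :]
        return dx


class AvgPool1D:
    """Non-overlapping average pooling along axis 1; trailing remainder dropped."""

    def __init__(self, pool: int):
        self.pool = pool
        self._in_len = None

    params: list = []

    def out_len(self, L: int) -> int:
        return L // self.pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, L, C = x.shape
        self._in_len = L
        Lo = L // self.pool
        return x[:, :Lo * self.pool, :].reshape(N, Lo, self.pool, C).mean(axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, Lo, C = g.shape
        dx = np.zeros((N, self._in_len, C), dtype=g.dtype)
        dx[:, :Lo * self.pool, :] = np.repeat(g / self.pool, self.pool, axis=1)
        return dx


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
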