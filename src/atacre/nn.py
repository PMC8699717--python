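"""Minimal neural-network layers in numpy.

Just the pieces the dual-branch classifier needs: 1-D convolution (stride 1,
valid padding) via im2col/col2im, batch normalization with running statistics,
max pooling, dense layers, a fused softmax/cross-entropy head, and the Adam
optimizer.  Everything is deterministic given a seeded ``numpy`` Generator,
and gradients are implemented analytically layer by layer.

Array layout: convolutional inputs are ``(batch, positions, channels)`` —
positions form the convolution axis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable array together with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution, stride 1, valid padding: (N, L, C_in) -> (N, L-k+1, C_out)."""

    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        fan_in = kernel * in_channels
        self.W = Param(glorot_uniform(rng, (fan_in, filters), fan_in, filters), "conv.W")
        self.b = Param(np.zeros(filters), "conv.b")
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, L, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if L < self.kernel:
            raise ValueError(f"input length {L} shorter than kernel {self.kernel}")
        self._in_len = L
        # (N, L_out, C, k) -> (N, L_out, k, C) -> (N*L_out, k*C)
        win = sliding_window_view(x, self.kernel, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            n * (L - self.kernel + 1), self.kernel * c
        )
        self._cols = cols if training else None
        out = cols @ self.W.value + self.b.value
        return out.reshape(n, L - self.kernel + 1, self.filters)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, L_out, f = grad.shape
        gflat = grad.reshape(n * L_out, f)
        self.W.grad += self._cols.T @ gflat
        self.b.grad += gflat.sum(axis=0)
        dcols = (gflat @ self.W.value.T).reshape(n, L_out, self.kernel, self.in_channels)
        dx = np.zeros((n, self._in_len, self.in_channels))
        for j in range(self.kernel):
            dx[:, j : j + L_out, :] += dcols[:, :, j, :]
        self._cols = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over the batch (and position) axes.

    Accepts (N, F) or (N, L, C) input; running statistics (momentum 0.9) are
    used outside training so inference is batch-composition independent.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat, self._inv, self._axes = xhat, inv, axes
            self._m = x.size // x.shape[-1]
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes, xhat, inv, m = self._axes, self._xhat, self._inv, self._m
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        return inv * (
            g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes)
        )


class MaxPool1D(Layer):
    """(N, L, C) -> (N, floor(L/pool), C); a trailing remainder is dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, L, c = x.shape
        L2 = (L // self.pool) * self.pool
        self._in_shape = x.shape
        blocks = x[:, :L2, :].reshape(n, L2 // self.pool, self.pool, c)
        self._argmax = blocks.argmax(axis=2)
        return blocks.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, L_out, c = grad.shape
        dx = np.zeros(self._in_shape)
        blocks = dx[:, : L_out * self.pool, :].reshape(n, L_out, self.pool, c)
        ni, li, ci = np.ogrid[:n, :L_out, :c]
        blocks[ni, li, self._argmax, ci] = grad
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.W = Param(
            glorot_uniform(rng, (in_features, out_features), in_features, out_features),
            "dense.W",
        )
        self.b = Param(np.zeros(out_features), "dense.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        self._x = None
        return grad @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = probs.shape[0]
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())


def softmax_xent_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean cross-entropy)/d(logits) for a softmax output."""
    n = probs.shape[0]
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return grad / n


class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(
        self,
        params: list[Param],
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def snapshot_params(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def restore_params(params: list[Param], snapshot: list[np.ndarray]) -> None:
    for p, s in zip(params, snapshot):
        p.value[...] = s
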