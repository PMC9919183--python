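"""Minimal NumPy layers with manual backprop for the tiny fused classifier.

Only what the architecture needs: same-padded 1-D correlation, batch
normalization, tanh/relu, global max pooling, dense maps and a weighted
softmax cross-entropy head, plus Adam.  Conventions (initialisers, BN
epsilon/momentum, 'same' padding alignment) follow the common deep-learning
framework defaults so parameter counts and layer semantics line up with the
reference architecture tables.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv1DSame(Layer):
    """1-D correlation layer, stride 1, zero 'same' padding, one bias per kernel.

    Weights have shape ``(nk, cin, nf)``; for input of length L the output is
    ``y[b, n, f] = b_f + sum_{k,c} x[b, n - (nk-1)//2 + k, c] * W[k, c, f]``.
    """

    def __init__(self, nk: int, cin: int, nf: int, rng: np.random.Generator, trainable: bool = True):
        self.nk, self.cin, self.nf = nk, cin, nf
        w = glorot_uniform(rng, (nk, cin, nf), fan_in=nk * cin, fan_out=nk * nf)
        self.W = Param(w, trainable=trainable, name="conv/W")
        self.b = Param(np.zeros(nf), trainable=trainable, name="conv/b")
        self.pl = (nk - 1) // 2
        self.pr = nk // 2

    def set_kernels(self, kernels: np.ndarray) -> None:
        """Assign kernels given as (nf, nk) or (nf, nk, cin)."""
        kernels = np.asarray(kernels, dtype=np.float64)
        if kernels.ndim == 2:
            kernels = kernels[:, :, None]
        if kernels.shape != (self.nf, self.nk, self.cin):
            raise ValueError(
                f"kernel block {kernels.shape} does not match layer "
                f"(nf={self.nf}, nk={self.nk}, cin={self.cin})"
            )
        self.W.value = kernels.transpose(1, 2, 0).copy()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (self.pl, self.pr), (0, 0)))
        # (B, L, nk, cin) sliding windows
        xcol = np.lib.stride_tricks.sliding_window_view(xp, self.nk, axis=1)
        xcol = xcol.transpose(0, 1, 3, 2)
        self._xcol = xcol
        self._in_len = x.shape[1]
        return np.tensordot(xcol, self.W.value, axes=([2, 3], [0, 1])) + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += np.tensordot(self._xcol, dy, axes=([0, 1], [0, 1]))
        self.b.grad += dy.sum(axis=(0, 1))
        B, L, _ = dy.shape
        dxp = np.zeros((B, L + self.pl + self.pr, self.cin))
        for k in range(self.nk):
            dxp[:, k : k + L, :] += dy @ self.W.value[k].T
        return dxp[:, self.pl : self.pl + self._in_len, :]

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm(Layer):
    """Channel-wise batch normalization over the batch (and time) axes."""

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.99):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels), name="bn/gamma")
        self.beta = Param(np.zeros(channels), name="bn/beta")
        self.moving_mean = Param(np.zeros(channels), trainable=False, name="bn/moving_mean")
        self.moving_var = Param(np.ones(channels), trainable=False, name="bn/moving_var")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean.value = m * self.moving_mean.value + (1 - m) * mean
            self.moving_var.value = m * self.moving_var.value + (1 - m) * var
        else:
            mean = self.moving_mean.value
            var = self.moving_var.value
        self._axes = axes
        self._n = x.size // x.shape[-1]
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = self._axes
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma.value * self._inv_std
        n = self._n
        dxhat = dy * self.gamma.value
        return (
            self._inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta, self.moving_mean, self.moving_var]


class Tanh(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalMaxPool(Layer):
    """Max over the time axis: (B, L, C) -> (B, C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._argmax = x.argmax(axis=1)
        self._shape = x.shape
        return np.take_along_axis(x, self._argmax[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        np.put_along_axis(dx, self._argmax[:, None, :], dy[:, None, :], axis=1)
        return dx


class Dense(Layer):
    """Affine map on the last axis: (..., cin) -> (..., cout)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "dense"):
        self.W = Param(glorot_uniform(rng, (cin, cout), cin, cout), name=f"{name}/W")
        self.b = Param(np.zeros(cout), name=f"{name}/b")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    probs: np.ndarray, y: np.ndarray, sample_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean weighted categorical cross-entropy and its gradient w.r.t. logits."""
    n = y.shape[0]
    p = np.clip(probs[np.arange(n), y], 1e-12, None)
    loss = float(np.mean(sample_weights * -np.log(p)))
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (sample_weights / n)[:, None]
    return loss, dlogits


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self._all_params = list(params)
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self._all_params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
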