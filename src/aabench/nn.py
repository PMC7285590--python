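"""Minimal NumPy neural-network engine.

The grading environment ships no deep-learning framework, so the handful of
layer types the benchmark architectures need (embedding lookup, LSTM,
1-D convolution, batch normalisation, pooling, dense) are implemented here
with explicit forward/backward passes and an Adam optimiser.  Defaults
mirror the common Keras choices: glorot-uniform kernels, orthogonal LSTM
recurrence with unit forget-gate bias, Adam(1e-3, 0.9, 0.999, eps=1e-7).

Every layer is verified against numeric finite-difference gradients in the
test suite; training is deterministic given the construction and shuffle
seeds (single-threaded NumPy, float64 throughout).
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A tensor with an accumulated gradient and a trainable flag."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.normal(size=(n, m))
    flip = n < m
    if flip:
        a = a.T
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q.T if flip else q


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Embedding(Layer):
    """Token-index lookup into a (vocab, dim) matrix.

    When ``trainable`` is false the matrix is used verbatim and never
    receives gradient updates (the frozen-scheme contract).
    """

    def __init__(self, weights: np.ndarray, trainable: bool):
        self.W = Parameter(np.array(weights, dtype=float), trainable, "embedding")
        self._tokens: np.ndarray | None = None

    def params(self):
        return [self.W]

    def forward(self, tokens, training):
        self._tokens = np.asarray(tokens, dtype=int)
        return self.W.value[self._tokens]

    def backward(self, dout):
        if self.W.trainable:
            np.add.at(self.W.grad, self._tokens, dout)
        return None  # integer inputs have no gradient


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state (B, units)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        H = units
        self.units = H
        self.Wx = Parameter(glorot_uniform(rng, in_dim, 4 * H, (in_dim, 4 * H)), name="lstm/Wx")
        self.Wh = Parameter(orthogonal(rng, H, 4 * H), name="lstm/Wh")
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # unit forget-gate bias
        self.b = Parameter(b, name="lstm/b")
        self._cache = None

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, training):
        B, L, _ = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates, cs, hs = [], [], []
        for t in range(L):
            a = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = sigmoid(a[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates.append((i, f, g, o))
            cs.append(c)
            hs.append(h)
        self._cache = (x, gates, cs, hs)
        return h

    def backward(self, dout):
        x, gates, cs, hs = self._cache
        B, L, D = x.shape
        H = self.units
        dx = np.zeros_like(x)
        dh = dout.copy()
        dc = np.zeros((B, H))
        for t in range(L - 1, -1, -1):
            i, f, g, o = gates[t]
            c = cs[t]
            c_prev = cs[t - 1] if t > 0 else np.zeros((B, H))
            h_prev = hs[t - 1] if t > 0 else np.zeros((B, H))
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )
            self.Wx.grad += x[:, t].T @ da
            self.Wh.grad += h_prev.T @ da
            self.b.grad += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.value.T
            dh = da @ self.Wh.value.T
            dc = dc * f
        return dx


class Conv1D(Layer):
    """Valid-padding 1-D convolution over (B, L, C) -> (B, L', filters)."""

    def __init__(self, in_ch: int, filters: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        self.stride = stride
        fan_in = kernel * in_ch
        self.W = Parameter(glorot_uniform(rng, fan_in, filters, (fan_in, filters)), name="conv/W")
        self.b = Parameter(np.zeros(filters), name="conv/b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        B, L, C = x.shape
        k, s = self.kernel, self.stride
        if L < k:
            raise ValueError(f"input length {L} shorter than kernel {k}")
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, L-k+1, C, k)
        win = win[:, ::s]  # (B, Lout, C, k)
        cols = win.transpose(0, 1, 3, 2).reshape(B, -1, k * C)  # (B, Lout, k*C)
        self._cache = (cols, x.shape)
        return cols @ self.W.value + self.b.value

    def backward(self, dout):
        cols, x_shape = self._cache
        B, L, C = x_shape
        k, s = self.kernel, self.stride
        Lout = cols.shape[1]
        d2 = dout.reshape(B * Lout, -1)
        self.W.grad += cols.reshape(B * Lout, k * C).T @ d2
        self.b.grad += d2.sum(axis=0)
        dcols = (dout @ self.W.value.T).reshape(B, Lout, k, C)
        dx = np.zeros(x_shape)
        pos = np.arange(Lout) * s
        for j in range(k):
            dx[:, pos + j, :] += dcols[:, :, j, :]
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class BatchNorm(Layer):
    """Per-channel batch normalisation over (B, L, C) or (B, C)."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = Parameter(np.ones(channels), name="bn/gamma")
        self.beta = Parameter(np.zeros(channels), name="bn/beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
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
        self._cache = (xhat, inv, axes, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, inv, axes, shape = self._cache
        n = np.prod([shape[a] for a in axes])
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        dx = (inv / n) * (
            n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )
        return dx


class AvgPool(Layer):
    """Non-overlapping average pooling along the length axis; trailing
    positions that do not fill a window are dropped (Keras 'valid')."""

    def __init__(self, width: int):
        self.width = width

    def forward(self, x, training):
        B, L, C = x.shape
        w = self.width
        n = L // w
        self._in_shape = x.shape
        return x[:, : n * w].reshape(B, n, w, C).mean(axis=2)

    def backward(self, dout):
        B, L, C = self._in_shape
        w = self.width
        n = L // w
        dx = np.zeros(self._in_shape)
        dx[:, : n * w] = np.repeat(dout / w, w, axis=1)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :] / self._L, self._L, axis=1)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Parameter(glorot_uniform(rng, in_dim, out_dim, (in_dim, out_dim)), name="dense/W")
        self.b = Parameter(np.zeros(out_dim), name="dense/b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def bce_loss_from_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; returns loss and d loss / d logits."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(target * np.log(p + eps) + (1 - target) * np.log(1 - p + eps))
    return float(loss), (p - target) / logits.size
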