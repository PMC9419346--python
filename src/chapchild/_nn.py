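"""Minimal numpy neural-network layers for the posture classifier.

Implements exactly what the CNN-BiLSTM topology needs — 1-D convolution,
ReLU, max pooling, global average pooling, dropout, dense layers, a
bidirectional LSTM, softmax cross-entropy and Adam — with analytic backward
passes. Everything is float64, single-threaded-deterministic given a seeded
``numpy.random.Generator``, and gradient-checked in the test suite.

Array conventions: convolutional inputs are (N, L, C) = (batch, length,
channels); recurrent inputs are (N, T, D) = (batch, steps, features).
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: parameters live in ``params``; gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv1d(Layer):
    """Valid (no-padding) stride-1 1-D convolution, (N, L, Cin) → (N, L-K+1, Cout)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel < 1:
            raise ValueError("conv kernel must be >= 1")
        self.k, self.c_in, self.c_out = kernel, c_in, c_out
        self.params["W"] = _glorot(rng, (kernel * c_in, c_out), kernel * c_in, c_out)
        self.params["b"] = np.zeros(c_out)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, _ = x.shape
        lout = length - self.k + 1
        # im2col: (N, Lout, K, Cin) view, no copy
        cols = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        cols = cols.transpose(0, 1, 3, 2).reshape(n, lout, self.k * self.c_in)
        self._x_shape, self._cols = x.shape, cols
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, lout, _ = dy.shape
        cols2 = self._cols.reshape(-1, self.k * self.c_in)
        dy2 = dy.reshape(-1, self.c_out)
        self.grads["W"] += cols2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        dcols = (dy2 @ self.params["W"].T).reshape(n, lout, self.k, self.c_in)
        dx = np.zeros(self._x_shape)
        for j in range(self.k):
            dx[:, j : j + lout, :] += dcols[:, :, j, :]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the length axis (trailing remainder dropped)."""

    def __init__(self, pool: int):
        super().__init__()
        if pool < 1:
            raise ValueError("pool size must be >= 1")
        self.p = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        lout = length // self.p
        xr = x[:, : lout * self.p, :].reshape(n, lout, self.p, c)
        self._arg = xr.argmax(axis=2)
        self._x_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, lout, c = dy.shape
        dx = np.zeros(self._x_shape)
        dxr = dx[:, : lout * self.p, :].reshape(n, lout, self.p, c)
        ni, li, ci = np.ogrid[:n, :lout, :c]
        dxr[ni, li, self._arg, ci] = dy
        return dx


class GlobalAvgPool(Layer):
    """(N, L, C) → (N, C) by mean over the length axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._l = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._l, axis=1) / self._l


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.params["b"] = np.zeros(d_out)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class LSTM(Layer):
    """Unidirectional LSTM, (N, T, D) → (N, T, H); gate order i, f, g, o."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.h = hidden
        self.params["Wx"] = _glorot(rng, (d_in, 4 * hidden), d_in, hidden)
        self.params["Wh"] = _glorot(rng, (hidden, 4 * hidden), hidden, hidden)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.params["b"] = b
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        h = self.h
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        hs = np.zeros((n, t, h))
        self._cache = []
        h_prev = np.zeros((n, h))
        c_prev = np.zeros((n, h))
        xz = x @ Wx  # precompute the input contribution for all steps
        for step in range(t):
            z = xz[:, step, :] + h_prev @ Wh + b
            i = sigmoid(z[:, :h])
            f = sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = sigmoid(z[:, 3 * h :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            hs[:, step, :] = o * tc
            self._cache.append((x[:, step, :], h_prev, c_prev, i, f, g, o, tc))
            h_prev, c_prev = hs[:, step, :], c
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        n, t, _ = dhs.shape
        h = self.h
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros((n, t, Wx.shape[0]))
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for step in reversed(range(t)):
            x_t, h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            dh = dhs[:, step, :] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = np.empty((n, 4 * h))
            dz[:, :h] = dc * g * i * (1.0 - i)
            dz[:, h : 2 * h] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * h : 3 * h] = dc * i * (1.0 - g * g)
            dz[:, 3 * h :] = dh * tc * o * (1.0 - o)
            self.grads["Wx"] += x_t.T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, step, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Concatenated forward and time-reversed LSTM passes, (N, T, D) → (N, T, 2H)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(d_in, hidden, rng)
        self.bwd = LSTM(d_in, hidden, rng)

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]

    def zero_grad(self) -> None:
        for sl in self.sublayers:
            sl.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h = self.fwd.h
        dxf = self.fwd.backward(dy[:, :, :h])
        dxb = self.bwd.backward(dy[:, ::-1, h:])[:, ::-1, :]
        return dxf + dxb


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over all positions; returns (loss, dlogits).

    ``logits``: (..., C); ``labels``: integer array matching the leading shape.
    """
    p = softmax(logits)
    flat_p = p.reshape(-1, p.shape[-1])
    flat_y = labels.reshape(-1)
    n = flat_y.size
    eps = 1e-12
    loss = -np.log(flat_p[np.arange(n), flat_y] + eps).mean()
    dlogits = flat_p.copy()
    dlogits[np.arange(n), flat_y] -= 1.0
    return loss, (dlogits / n).reshape(logits.shape)


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [sl for l in layers for sl in (l.sublayers if isinstance(l, BiLSTM) else [l])]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                mh = self.m[li][k] / (1 - self.b1**self.t)
                vh = self.v[li][k] / (1 - self.b2**self.t)
                p -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()
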