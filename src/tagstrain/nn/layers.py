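"""Minimal CPU neural-network building blocks with explicit backpropagation.

Layers store their parameters as :class:`Param` objects (value + accumulated
gradient) and cache whatever the backward pass needs.  Shapes follow the
(N, C, H, W) convention for images and (T, N, D) for sequences.  Everything is
plain numpy so training is bit-reproducible for a fixed seed on one machine.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=float)
        self.g = np.zeros_like(self.v)


class Layer:
    def params(self):
        return []

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train: bool = False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class Conv2d(Layer):
    """3x3-style convolution via im2col; stride and zero padding supported."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(_he_init(rng, (c_out, c_in * k * k), c_in * k * k))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train: bool = False):
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # (N, C, Ho, Wo, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
        y = cols @ self.W.v.T + self.b.v
        self._cache = (cols, (N, C, H, W, Ho, Wo))
        return y.reshape(N, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, (N, C, H, W, Ho, Wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dyf = dy.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, self.c_out)
        self.W.g += dyf.T @ cols
        self.b.g += dyf.sum(axis=0)
        dcols = (dyf @ self.W.v).reshape(N, Ho, Wo, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W] if p else dxp


class AvgPool2d(Layer):
    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train: bool = False):
        N, C, H, W = x.shape
        k = self.k
        self._shape = x.shape
        return x.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(self, dy):
        N, C, H, W = self._shape
        k = self.k
        return np.repeat(np.repeat(dy, k, axis=2), k, axis=3) / (k * k)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool = False):
        g = self.gamma.v[None, :, None, None]
        b = self.beta.v[None, :, None, None]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.run_mean = m * self.run_mean + (1 - m) * mu
            self.run_var = m * self.run_var + (1 - m) * var
        else:
            mu, var = self.run_mean, self.run_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, train)
        return g * xhat + b

    def backward(self, dy):
        xhat, ivar, train = self._cache
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dy.sum(axis=(0, 2, 3))
        g = self.gamma.v[None, :, None, None]
        dxhat = dy * g
        if not train:
            return dxhat * ivar[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (ivar[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Flatten(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(_he_init(rng, (d_in, d_out), d_in))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dy):
        self.W.g += self._x.T @ dy
        self.b.g += dy.sum(axis=0)
        return dy @ self.W.v.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train: bool = False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class LSTM(Layer):
    """Single-layer LSTM over a (T, N, D) sequence, full BPTT.

    Gate layout in the fused weight matrices is (input, forget, cell, output).
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.d_in, self.hidden = d_in, hidden
        scale = 1.0 / np.sqrt(d_in + hidden)
        self.Wx = Param(rng.normal(0.0, scale, (d_in, 4 * hidden)))
        self.Wh = Param(rng.normal(0.0, scale, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train: bool = False):
        T, N, D = x.shape
        H = self.hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        self._caches = []
        self._x = x
        out = np.empty((T, N, H))
        for t in range(T):
            z = x[t] @ self.Wx.v + h @ self.Wh.v + self.b.v
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[t] = h
            self._caches.append((i, f, g, o, c_prev, tc, h))
        return out

    def backward(self, dout):
        T, N, _ = self._x.shape
        H = self.hidden
        dx = np.empty_like(self._x)
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in reversed(range(T)):
            i, f, g, o, c_prev, tc, h = self._caches[t]
            h_prev = self._caches[t - 1][6] if t > 0 else np.zeros((N, H))
            dh = dout[t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1)
            self.Wx.g += self._x[t].T @ dz
            self.Wh.g += h_prev.T @ dz
            self.b.g += dz.sum(axis=0)
            dx[t] = dz @ self.Wx.v.T
            dh_next = dz @ self.Wh.v.T
        return dx


class Adam:
    """Adam optimizer over a parameter list; gradients are zeroed after a step."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.v = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.g
            v *= self.b2
            v += (1 - self.b2) * p.g**2
            p.v -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.g[...] = 0.0

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0
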