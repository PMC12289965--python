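"""Minimal CPU neural-network layers with explicit backprop.

Small by design: the classification harness trains compact convolutional,
recurrent and attention models on desk-scale synthetic data, so a few
hand-written layers with Adam updates are sufficient and keep the package
free of heavyweight framework dependencies.  Shapes follow the (N, C, H, W)
convention; sequence models consume (N, T, ...) and share their frame
encoder across timepoints.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def adam_step(params: list[Param], lr: float, t: int,
              beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
    for p in params:
        p.m = beta1 * p.m + (1 - beta1) * p.grad
        p.v = beta2 * p.v + (1 - beta2) * p.grad * p.grad
        mhat = p.m / (1 - beta1 ** t)
        vhat = p.v / (1 - beta2 ** t)
        p.value -= lr * mhat / (np.sqrt(vhat) + eps)


def zero_grads(params: list[Param]) -> None:
    for p in params:
        p.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class AvgPoolDown(Layer):
    """Fixed average-pool downsampling by an integer factor (no params)."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x):
        f = self.factor
        if f == 1:
            return x
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, gy):
        f = self.factor
        if f == 1:
            return gy
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(gy, f, axis=2), f, axis=3) / (f * f)
        return g


class Conv2d(Layer):
    """3x3 same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        scale = math.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))
        self.k = k

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        n, c, h, w = x.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
        return cols

    def forward(self, x):
        self._xshape = x.shape
        n, c, h, w = x.shape
        self._cols = self._im2col(x)
        w2 = self.W.value.reshape(self.W.value.shape[0], -1)
        y = self._cols @ w2.T + self.b.value  # (N, H*W, c_out)
        return y.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, gy):
        n, c, h, w = self._xshape
        c_out = gy.shape[1]
        gy2 = gy.reshape(n, c_out, h * w).transpose(0, 2, 1)  # (N, HW, c_out)
        w2 = self.W.value.reshape(c_out, -1)
        gw = np.einsum("npq,npk->qk", gy2, self._cols)
        self.W.grad += gw.reshape(self.W.value.shape)
        self.b.grad += gy2.sum(axis=(0, 1))
        gcols = gy2 @ w2  # (N, HW, C*k*k)
        k = self.k
        pad = k // 2
        gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        gcols = gcols.reshape(n, h, w, c, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + h, dj:dj + w] += gcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2)
        return gx[:, :, pad:pad + h, pad:pad + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y * self._y)


class MaxPool2(Layer):
    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        mask = xr == y[:, :, :, None, :, None]
        # break ties: keep only the first max in each 2x2 window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        flat = flat & first
        self._mask = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5)
        return y

    def backward(self, gy):
        n, c, h, w = self._shape
        g = self._mask * gy[:, :, :, None, :, None]
        return g.reshape(n, c, h, w)


class GlobalAvgMaxPool(Layer):
    """Concatenate global average and max pooling -> (N, 2C)."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        xf = x.reshape(n, c, h * w)
        avg = xf.mean(axis=2)
        idx = xf.argmax(axis=2)
        self._argmax = idx
        mx = np.take_along_axis(xf, idx[:, :, None], axis=2)[:, :, 0]
        return np.concatenate([avg, mx], axis=1)

    def backward(self, gy):
        n, c, h, w = self._shape
        gavg, gmax = gy[:, :c], gy[:, c:]
        gx = np.repeat(gavg[:, :, None], h * w, axis=2) / (h * w)
        np.put_along_axis(
            gx, self._argmax[:, :, None],
            np.take_along_axis(gx, self._argmax[:, :, None], axis=2)
            + gmax[:, :, None], axis=2)
        return gx.reshape(n, c, h, w)


class FeatureNorm(Layer):
    """Frozen feature standardization (x - mu) / sd before the classifier head.

    Statistics are set once from the training set (see ``Sequential.calibrate``)
    and kept fixed, like a frozen batch norm: they remove the large common
    activation offset so the head only has to learn the class direction.
    """

    def __init__(self, d: int):
        self.mu = np.zeros(d)
        self.sd = np.ones(d)
        self.initialized = False

    def set_stats(self, feats: np.ndarray) -> None:
        flat = feats.reshape(-1, feats.shape[-1])
        self.mu = flat.mean(axis=0)
        self.sd = np.maximum(flat.std(axis=0), 1e-6)
        self.initialized = True

    def buffers(self) -> list[np.ndarray]:
        return [self.mu, self.sd]

    def forward(self, x):
        return (x - self.mu) / self.sd

    def backward(self, gy):
        return gy / self.sd


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        # zero_init suits classifier heads: logits start at 0 (p = 0.5)
        scale = 0.0 if zero_init else math.sqrt(1.0 / d_in)
        self.W = Param(rng.normal(0.0, 1.0, size=(d_in, d_out)) * scale)
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        # supports (N, D) and (N, T, D) inputs
        x = self._x
        if x.ndim == 2:
            self.W.grad += x.T @ gy
            self.b.grad += gy.sum(axis=0)
        else:
            self.W.grad += np.einsum("ntd,nte->de", x, gy)
            self.b.grad += gy.sum(axis=(0, 1))
        return gy @ self.W.value.T


class Patchify(Layer):
    """(N, C, H, W) -> (N, (H/p)(W/p), C*p*p) tokens."""

    def __init__(self, patch: int):
        self.p = patch

    def forward(self, x):
        p = self.p
        n, c, h, w = x.shape
        self._shape = x.shape
        xr = x.reshape(n, c, h // p, p, w // p, p)
        return xr.transpose(0, 2, 4, 1, 3, 5).reshape(n, (h // p) * (w // p),
                                                      c * p * p)

    def backward(self, gy):
        p = self.p
        n, c, h, w = self._shape
        g = gy.reshape(n, h // p, w // p, c, p, p).transpose(0, 3, 1, 4, 2, 5)
        return g.reshape(n, c, h, w)


class PositionalEmbedding(Layer):
    """Learnable additive position embedding for (N, T, D) tokens."""

    def __init__(self, n_tokens: int, d: int, rng: np.random.Generator):
        self.P = Param(rng.normal(0.0, 0.1, size=(n_tokens, d)))

    def params(self):
        return [self.P]

    def forward(self, x):
        return x + self.P.value

    def backward(self, gy):
        self.P.grad += gy.sum(axis=0)
        return gy


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SelfAttention(Layer):
    """Single-head scaled dot-product self-attention over tokens (N, T, D)."""

    def __init__(self, d: int, rng: np.random.Generator):
        scale = math.sqrt(1.0 / d)
        self.Wq = Param(rng.normal(0.0, scale, size=(d, d)))
        self.Wk = Param(rng.normal(0.0, scale, size=(d, d)))
        self.Wv = Param(rng.normal(0.0, scale, size=(d, d)))
        self.Wo = Param(rng.normal(0.0, scale, size=(d, d)))
        self.d = d

    def params(self):
        return [self.Wq, self.Wk, self.Wv, self.Wo]

    def forward(self, x):
        self._x = x
        d = self.d
        q = x @ self.Wq.value
        k = x @ self.Wk.value
        v = x @ self.Wv.value
        att = _softmax(q @ k.transpose(0, 2, 1) / math.sqrt(d))
        ctx = att @ v
        self._q, self._k, self._v, self._att, self._ctx = q, k, v, att, ctx
        return ctx @ self.Wo.value + x  # residual connection

    def backward(self, gy):
        x, q, k, v, att, ctx = self._x, self._q, self._k, self._v, self._att, self._ctx
        d = self.d
        self.Wo.grad += np.einsum("ntd,nte->de", ctx, gy)
        gctx = gy @ self.Wo.value.T
        gatt = gctx @ v.transpose(0, 2, 1)
        gv = att.transpose(0, 2, 1) @ gctx
        # softmax backward
        gz = att * (gatt - (gatt * att).sum(axis=-1, keepdims=True))
        gz = gz / math.sqrt(d)
        gq = gz @ k
        gk = gz.transpose(0, 2, 1) @ q
        self.Wq.grad += np.einsum("ntd,nte->de", x, gq)
        self.Wk.grad += np.einsum("ntd,nte->de", x, gk)
        self.Wv.grad += np.einsum("ntd,nte->de", x, gv)
        gx = gq @ self.Wq.value.T + gk @ self.Wk.value.T + gv @ self.Wv.value.T
        return gx + gy  # residual path


class MeanTokens(Layer):
    """(N, T, D) -> (N, D) mean over tokens."""

    def forward(self, x):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, gy):
        return np.repeat(gy[:, None, :], self._t, axis=1) / self._t


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out: list[Param] = []
        for lyr in self.layers:
            out.extend(lyr.params())
        return out

    def buffers(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for lyr in self.layers:
            if hasattr(lyr, "buffers"):
                out.extend(lyr.buffers())
            elif isinstance(lyr, (Sequential, FrameEncoderSequence)):
                out.extend(lyr.buffers())
        return out

    def forward(self, x):
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, gy):
        for lyr in reversed(self.layers):
            gy = lyr.backward(gy)
        return gy

    def calibrate(self, x) -> None:
        """Initialize any FeatureNorm statistics from a data pass."""
        for lyr in self.layers:
            if isinstance(lyr, FeatureNorm) and not lyr.initialized:
                lyr.set_stats(x)
            if isinstance(lyr, (Sequential, FrameEncoderSequence)):
                lyr.calibrate(x)
                x = lyr.forward(x)
            else:
                x = lyr.forward(x)


class SimpleRNN(Layer):
    """tanh recurrence over a feature sequence (N, T, F) -> (N, H) last state."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.Wx = Param(rng.normal(0.0, math.sqrt(1.0 / d_in), (d_in, d_hidden)))
        self.Wh = Param(rng.normal(0.0, math.sqrt(1.0 / d_hidden),
                                   (d_hidden, d_hidden)))
        self.b = Param(np.zeros(d_hidden))
        self.d_hidden = d_hidden

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x):
        n, t, _ = x.shape
        self._x = x
        hs = [np.zeros((n, self.d_hidden))]
        for k in range(t):
            h = np.tanh(x[:, k] @ self.Wx.value + hs[-1] @ self.Wh.value
                        + self.b.value)
            hs.append(h)
        self._hs = hs
        return hs[-1]

    def backward(self, gy):
        x, hs = self._x, self._hs
        n, t, d_in = x.shape
        gx = np.zeros_like(x)
        gh = gy
        for k in range(t - 1, -1, -1):
            h = hs[k + 1]
            gz = gh * (1.0 - h * h)
            self.Wx.grad += x[:, k].T @ gz
            self.Wh.grad += hs[k].T @ gz
            self.b.grad += gz.sum(axis=0)
            gx[:, k] = gz @ self.Wx.value.T
            gh = gz @ self.Wh.value.T
        return gx


class FrameEncoderSequence(Layer):
    """Apply a shared frame encoder to each timepoint of (N, T, C, H, W)."""

    def __init__(self, encoder: Sequential):
        self.encoder = encoder

    def params(self):
        return self.encoder.params()

    def buffers(self):
        return self.encoder.buffers()

    def calibrate(self, x) -> None:
        n, t = x.shape[:2]
        self.encoder.calibrate(x.reshape((n * t,) + x.shape[2:]))

    def forward(self, x):
        n, t = x.shape[:2]
        self._nt = (n, t)
        flat = x.reshape((n * t,) + x.shape[2:])
        feats = self.encoder.forward(flat)
        return feats.reshape(n, t, -1)

    def backward(self, gy):
        n, t = self._nt
        g = self.encoder.backward(gy.reshape((n * t,) + gy.shape[2:]))
        return g.reshape((n, t) + g.shape[1:])


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and gradient w.r.t. logits."""
    z = z.reshape(-1)
    y = y.reshape(-1).astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (sigmoid(z) - y) / len(z)
    return loss, grad
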