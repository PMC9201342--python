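"""Layers with explicit forward/backward passes.

Shapes are channels-first: ``(N, C, H, W)``.  Each layer caches whatever its
backward pass needs during ``forward``; one ``backward`` call consumes that
cache, so forward/backward calls must alternate (the training loop does).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array and its current gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Module):
    """k x k convolution, stride 1, 'same' padding, via im2col + GEMM."""

    def __init__(self, in_ch, out_ch, rng, k=3, bias=True, dtype=np.float32):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = k // 2
        self.W = Param(_he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype)) if bias else None
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        wmat = self.W.data.reshape(self.out_ch, -1)
        out = cols @ wmat.T
        if self.b is not None:
            out += self.b.data
        self._cols, self._xshape = cols, x.shape
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c, h, w = self._xshape
        k, p = self.k, self.pad
        doutf = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.out_ch
        )
        self.W.grad = (doutf.T @ self._cols).reshape(self.W.data.shape)
        if self.b is not None:
            self.b.grad = doutf.sum(axis=0)
        dcols = (doutf @ self.W.data.reshape(self.out_ch, -1)).reshape(
            n, h, w, c, k, k
        )
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        dwin = dcols.transpose(0, 3, 1, 2, 4, 5)  # N,C,H,W,k,k
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dwin[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class DepthwiseConv2d(Module):
    """Per-channel k x k convolution (the depthwise half of a separable conv)."""

    def __init__(self, channels, rng, k=3, bias=True, dtype=np.float32):
        self.channels, self.k = channels, k
        self.pad = k // 2
        self.W = Param(_he_init(rng, (channels, k, k), k * k, dtype))
        self.b = Param(np.zeros(channels, dtype=dtype)) if bias else None
        self._win = None
        self._xshape = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
        out = np.einsum("nchwij,cij->nchw", win, self.W.data, optimize=True)
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        self._win, self._xshape = win, x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._xshape
        k, p = self.k, self.pad
        self.W.grad = np.einsum("nchw,nchwij->cij", dout, self._win, optimize=True)
        if self.b is not None:
            self.b.grad = dout.sum(axis=(0, 2, 3))
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += (
                    dout * self.W.data[None, :, i, j, None, None]
                )
        self._win = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class SeparableConv2d(Module):
    """Depthwise k x k followed by pointwise 1 x 1 (MobileNet-style)."""

    def __init__(self, in_ch, out_ch, rng, k=3, bias=True, dtype=np.float32):
        self.dw = DepthwiseConv2d(in_ch, rng, k=k, bias=False, dtype=dtype)
        self.pw = Conv2d(in_ch, out_ch, rng, k=1, bias=bias, dtype=dtype)

    def params(self):
        return self.dw.params() + self.pw.params()

    def forward(self, x, train=True):
        return self.pw.forward(self.dw.forward(x, train), train)

    def backward(self, dout):
        return self.dw.backward(self.pw.backward(dout))


class BatchNorm2d(Module):
    def __init__(self, channels, dtype=np.float32, eps=1e-5, momentum=0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]

    def backward(self, dout):
        xhat, invstd = self._cache
        n, c, h, w = dout.shape
        m = n * h * w
        self.gamma.grad = (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Module):
    """2x2 max pooling, stride 2.  Ties route gradient to the first maximum."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 3, 5)).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._idx = flat.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._xshape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class UpsampleNearest2d(Module):
    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h2, w2 = dout.shape
        return dout.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Softmax(Module):
    """Softmax over the channel axis; output is a per-pixel distribution."""

    def forward(self, x, train=True):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        self._p = p
        return p

    def backward(self, dout):
        p = self._p
        return p * (dout - (dout * p).sum(axis=1, keepdims=True))


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def params(self):
        return [p for m in self.modules for p in m.params()]

    def forward(self, x, train=True):
        for m in self.modules:
            x = m.forward(x, train)
        return x

    def backward(self, dout):
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout
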