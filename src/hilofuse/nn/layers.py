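"""Dense, convolutional, normalization and pooling layers."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import DTYPE, Module, Parameter


def he_normal(rng, fan_in, shape):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def xavier_uniform(rng, fan_in, fan_out, shape):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Linear(Module):
    """Affine map over the last axis; accepts any leading batch shape."""

    def __init__(self, n_in, n_out, rng, init="he"):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        if init == "he":
            w = he_normal(rng, n_in, (n_in, n_out))
        else:
            w = xavier_uniform(rng, n_in, n_out, (n_in, n_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x):
        if self.training:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        x2 = self._x.reshape(-1, self.n_in)
        g2 = grad.reshape(-1, self.n_out)
        self.weight.grad += x2.T @ g2
        self.bias.grad += g2.sum(axis=0)
        return (g2 @ self.weight.value.T).reshape(self._x.shape)


class ReLU(Module):
    def forward(self, x):
        y = np.maximum(x, 0.0)
        if self.training:
            self._mask = x > 0.0
        return y

    def backward(self, grad):
        return grad * self._mask


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate, rng):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        if self.rate == 0.0:
            return grad
        return grad * self._mask


class Conv3d(Module):
    """3D convolution via im2col + GEMM.

    Weight is stored GEMM-ready with shape (c_in * k^3, c_out).  The backward
    col2im scatter uses one bincount per sample, which is fast at the volume
    sizes used for training.
    """

    def __init__(self, c_in, c_out, kernel, rng, stride=None, pad=0):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k = kernel
        self.stride = stride if stride is not None else 1
        self.pad = pad
        fan_in = c_in * kernel ** 3
        self.weight = Parameter(he_normal(rng, fan_in, (fan_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))
        self._idx_cache = {}

    def _out_dim(self, d):
        return (d + 2 * self.pad - self.k) // self.stride + 1

    def _scatter_index(self, padded_shape, out_shape):
        key = (padded_shape, out_shape)
        if key not in self._idx_cache:
            dp, hp, wp = padded_shape
            do, ho, wo = out_shape
            k, s = self.k, self.stride
            od, oh, ow = np.meshgrid(
                np.arange(do) * s, np.arange(ho) * s, np.arange(wo) * s,
                indexing="ij",
            )
            base = (od * hp + oh) * wp + ow  # (do,ho,wo)
            kd, kh, kw = np.meshgrid(
                np.arange(k), np.arange(k), np.arange(k), indexing="ij")
            koff = ((kd * hp + kh) * wp + kw).ravel()  # (k^3,)
            self._idx_cache[key] = (base.ravel()[:, None] + koff[None, :]).ravel()
        return self._idx_cache[key]

    def forward(self, x):
        n, c, d, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (self.k,) * 3, axis=(2, 3, 4))
        s = self.stride
        win = win[:, :, ::s, ::s, ::s]
        do, ho, wo = win.shape[2:5]
        cols = np.ascontiguousarray(
            win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
        ).reshape(n * do * ho * wo, self.c_in * self.k ** 3)
        out = cols @ self.weight.value + self.bias.value
        if self.training:
            self._cols = cols
            self._in_shape = x.shape
            self._padded_spatial = xp.shape[2:]
            self._out_spatial = (do, ho, wo)
        return np.ascontiguousarray(
            out.reshape(n, do, ho, wo, self.c_out).transpose(0, 4, 1, 2, 3))

    def backward(self, grad):
        n = self._in_shape[0]
        do, ho, wo = self._out_spatial
        gmat = np.ascontiguousarray(
            grad.transpose(0, 2, 3, 4, 1)).reshape(-1, self.c_out)
        self.weight.grad += self._cols.T @ gmat
        self.bias.grad += gmat.sum(axis=0)
        gcols = gmat @ self.weight.value.T  # (n*P, c_in*k^3)
        k3 = self.k ** 3
        p_out = do * ho * wo
        flat = self._scatter_index(self._padded_spatial, self._out_spatial)
        dp, hp, wp = self._padded_spatial
        s_pad = dp * hp * wp
        gc = gcols.reshape(n, p_out, self.c_in, k3).transpose(0, 2, 1, 3)
        chan_off = np.arange(self.c_in)[:, None] * s_pad
        idx_full = (chan_off + flat[None, :].reshape(1, -1)).ravel()
        gxp = np.empty((n, self.c_in * s_pad), dtype=DTYPE)
        for i in range(n):
            gxp[i] = np.bincount(
                idx_full, weights=gc[i].ravel(), minlength=self.c_in * s_pad)
        gxp = gxp.reshape(n, self.c_in, dp, hp, wp)
        p = self.pad
        if p:
            gxp = gxp[:, :, p:dp - p, p:hp - p, p:wp - p]
        self._cols = None
        return np.ascontiguousarray(gxp)


class MaxPool3d(Module):
    """Non-overlapping max pooling with cubic window (default 2)."""

    def __init__(self, window=2):
        super().__init__()
        self.w = window

    def forward(self, x):
        n, c, d, h, ww = x.shape
        k = self.w
        if d % k or h % k or ww % k:
            raise ValueError(
                f"spatial dims {(d, h, ww)} not divisible by pool window {k}")
        xr = x.reshape(n, c, d // k, k, h // k, k, ww // k, k)
        xr = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 6, 3, 5, 7))
        xr = xr.reshape(n, c, d // k, h // k, ww // k, k ** 3)
        if not self.training:
            return xr.max(axis=-1)
        am = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, am[..., None], axis=-1)[..., 0]
        self._am = am
        self._in_shape = x.shape
        return y

    def backward(self, grad):
        n, c, d, h, ww = self._in_shape
        k = self.w
        gwin = np.zeros((n, c, d // k, h // k, ww // k, k ** 3), dtype=DTYPE)
        np.put_along_axis(gwin, self._am[..., None], grad[..., None], axis=-1)
        gwin = gwin.reshape(n, c, d // k, h // k, ww // k, k, k, k)
        gwin = gwin.transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return np.ascontiguousarray(gwin.reshape(n, c, d, h, ww))


class BatchNorm3d(Module):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.set_buffer("running_mean", np.zeros(c, dtype=DTYPE))
        self.set_buffer("running_var", np.ones(c, dtype=DTYPE))

    def forward(self, x):
        axes = (0, 2, 3, 4)
        shape = (1, self.c, 1, 1, 1)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n_el = x.size // self.c
            m = self.momentum
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm *= 1 - m
            rm += m * mean
            rv *= 1 - m
            rv += m * var * (n_el / max(n_el - 1, 1))
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
            self._xhat = xhat
            self._invstd = invstd
            self._n_el = n_el
        else:
            # fused scale-and-shift with the running statistics
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            scale = self.gamma.value / np.sqrt(rv + self.eps)
            shift = self.beta.value - rm * scale
            return x * scale.reshape(shape) + shift.reshape(shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, grad):
        axes = (0, 2, 3, 4)
        shape = (1, self.c, 1, 1, 1)
        xhat, invstd, n_el = self._xhat, self._invstd, self._n_el
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.value.reshape(shape)
        t1 = gxhat.sum(axis=axes).reshape(shape)
        t2 = (gxhat * xhat).sum(axis=axes).reshape(shape)
        gx = (invstd.reshape(shape) / n_el) * (n_el * gxhat - t1 - xhat * t2)
        self._xhat = None
        return gx


class GlobalAvgPool3d(Module):
    """Mean over the spatial axes: (N, C, D, H, W) -> (N, C)."""

    def forward(self, x):
        if self.training:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        n, c, d, h, w = self._in_shape
        g = np.broadcast_to(
            grad[:, :, None, None, None] / (d * h * w), self._in_shape)
        return np.ascontiguousarray(g.astype(DTYPE))


class LayerNorm(Module):
    """Normalization over the last axis with affine parameters."""

    def __init__(self, d, eps=1e-5):
        super().__init__()
        self.d = d
        self.eps = eps
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))

    def forward(self, x):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if self.training:
            self._xhat = xhat
            self._invstd = invstd
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, invstd = self._xhat, self._invstd
        red = tuple(range(grad.ndim - 1))
        self.gamma.grad += (grad * xhat).sum(axis=red)
        self.beta.grad += grad.sum(axis=red)
        gxhat = grad * self.gamma.value
        d = self.d
        t1 = gxhat.sum(axis=-1, keepdims=True)
        t2 = (gxhat * xhat).sum(axis=-1, keepdims=True)
        gx = (invstd / d) * (d * gxhat - t1 - xhat * t2)
        self._xhat = None
        return gx
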