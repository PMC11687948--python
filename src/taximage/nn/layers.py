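"""Minimal NumPy layers with explicit forward/backward passes.

All activations are computed on (N, C, H, W) arrays.  Each layer caches what
its backward pass needs during forward; ``backward`` returns the gradient
with respect to the layer input and accumulates parameter gradients in-place
on :class:`Param` objects.  Convolutions use same-padding im2col with an odd
kernel, so output spatial size is ceil(input / stride).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "SpatialAttention",
    "GlobalAvgPool",
    "Linear",
]


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    h_out = (h + 2 * pad - k) // stride + 1
    w_out = (w + 2 * pad - k) // stride + 1
    windows = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h_out * w_out)
    return np.ascontiguousarray(cols), h_out, w_out


def _col2im(dcols, x_shape, k, stride, pad, h_out, w_out):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    dcols = dcols.reshape(n, c, k, k, h_out, w_out)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride] += dcols[
                :, :, i, j
            ]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d:
    """Same-padded 2D convolution (odd kernel), He-initialized."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, rng=None, name="conv"):
        if kernel_size % 2 != 1 or kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if stride < 1:
            raise ValueError("stride must be positive")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias")
        self.kernel_size = kernel_size
        self.stride = stride
        self.pad = kernel_size // 2
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def out_size(self, h, w):
        k, s, p = self.kernel_size, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x, train=False):
        cols, h_out, w_out = _im2col(x, self.kernel_size, self.stride, self.pad)
        w2 = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = np.einsum("ok,nkp->nop", w2, cols) + self.bias.value[None, :, None]
        self._cache = (cols, x.shape, h_out, w_out)
        return out.reshape(x.shape[0], -1, h_out, w_out)

    def backward(self, dout):
        cols, x_shape, h_out, w_out = self._cache
        n, c_out = dout.shape[:2]
        dout2 = dout.reshape(n, c_out, -1)
        self.bias.grad += dout2.sum(axis=(0, 2))
        self.weight.grad += np.einsum("nop,nkp->ok", dout2, cols).reshape(
            self.weight.value.shape
        )
        w2 = self.weight.value.reshape(c_out, -1)
        dcols = np.einsum("ok,nop->nkp", w2, dout2)
        return _col2im(
            dcols, x_shape, self.kernel_size, self.stride, self.pad, h_out, w_out
        )


class BatchNorm2d:
    def __init__(self, channels, momentum=0.9, eps=1e-5, name="bn"):
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:  # frozen statistics: plain affine map
            return dout * g * inv_std[None, :, None, None]
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / n) * (
            n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SpatialAttention:
    """CBAM-style spatial gate: sigmoid(conv_k([channel-mean; channel-max])).

    The attended output is the input scaled per-location by the gate,
    broadcast over channels.  ``bypass`` forces the gate to 1 (test hook).
    """

    def __init__(self, kernel_size=7, rng=None, name="attn"):
        self.conv = Conv2d(2, 1, kernel_size, stride=1, rng=rng, name=f"{name}.conv")
        self.bypass = False
        self._cache = None

    def params(self):
        return self.conv.params()

    def forward(self, x, train=False):
        if self.bypass:
            self.attention_map = np.ones((x.shape[0], 1) + x.shape[2:])
            self._cache = None
            return x
        mean_pool = x.mean(axis=1, keepdims=True)
        argmax = x.argmax(axis=1)
        max_pool = np.take_along_axis(x, argmax[:, None], axis=1)
        pooled = np.concatenate([mean_pool, max_pool], axis=1)
        z = self.conv.forward(pooled, train=train)
        a = _sigmoid(z)
        self.attention_map = a
        self._cache = (x, a, argmax)
        return x * a

    def backward(self, dout):
        if self._cache is None:  # bypassed forward
            return dout
        x, a, argmax = self._cache
        dx = dout * a
        da = (dout * x).sum(axis=1, keepdims=True)
        dz = da * a * (1.0 - a)
        dpooled = self.conv.backward(dz)
        dx += dpooled[:, 0:1] / x.shape[1]  # mean-pool branch
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, argmax[:, None], dpooled[:, 1:2], axis=1)
        return dx + dmax


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear:
    def __init__(self, in_features, out_features, rng=None, name="head"):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(
            rng.normal(0.0, std, (out_features, in_features)), name=f"{name}.weight"
        )
        self.bias = Param(np.zeros(out_features), name=f"{name}.bias")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value
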