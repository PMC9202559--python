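"""Minimal NCHW layer zoo with explicit forward/backward passes.

Every layer caches what its backward pass needs during forward; backward
accumulates parameter gradients in place and returns the input gradient.
All arithmetic is float32.  Convolutions are stride-1 with "same" padding
(or 1x1/valid), which is all the VGG19 U-Net requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class; layers without parameters inherit the empty default."""

    def parameters(self) -> list[tuple[str, Parameter]]:
        return []

    @property
    def num_params(self) -> int:
        return sum(p.size for _, p in self.parameters())


class Conv2d(Layer):
    """Stride-1 2D convolution with bias; 'same' padding for odd kernels."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        bias: bool = True,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(out_channels, in_channels, k, k))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.padding = k // 2
        self._cache = None

    def parameters(self):
        out = [("weight", self.weight)]
        if self.bias is not None:
            out.append(("bias", self.bias))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.kernel_size, self.padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        wmat = self.weight.value.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.kernel_size, self.padding
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.out_channels
        )
        self.weight.grad += (dmat.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dmat.sum(axis=0)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        dcols = dmat @ wmat  # (N*H*W, C*k*k)
        dcols = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for a in range(k):
            for b in range(k):
                dxp[:, :, a : a + h, b : b + w] += dcols[:, :, a, b]
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n, c, h, w = dout.shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        # standard batch-norm gradient over the per-channel sample dimension
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (
            inv_std[None, :, None, None]
            / m
            * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        )
        self._cache = None
        return dx.astype(np.float32)


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (inputs must have even spatial dims)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, (n, c, h, w))
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._cache = None
        return dx


class UpsampleNearest2x(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        return (
            dout.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)).astype(np.float32)
        )


class ConvBNReLU(Layer):
    """3x3 conv -> batch norm -> ReLU, the repeating unit of both paths."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.conv = Conv2d(in_channels, out_channels, 3, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.relu = ReLU()

    def parameters(self):
        return [
            (f"conv.{n}", p) for n, p in self.conv.parameters()
        ] + [(f"bn.{n}", p) for n, p in self.bn.parameters()]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x), training))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))
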