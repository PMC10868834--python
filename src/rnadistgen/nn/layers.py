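from __future__ import annotations

import numpy as np

from .core import Module, Parameter


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """Stride-1, same-padded 2D convolution (NHWC), optional dilation.

    Implemented with an explicit patch gather (im2col) and a single
    matmul; the input gradient is computed as a convolution of the
    output gradient with the spatially flipped, channel-transposed
    kernel, which for stride 1 and symmetric padding is exact.
    """

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.kernel, self.dilation = cin, cout, kernel, dilation
        fan_in = kernel * kernel * cin
        if zero_init:
            w = np.zeros((fan_in, cout), dtype=np.float32)
        else:
            w = _he_init(rng, fan_in, (fan_in, cout))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))
        self._cache = None

    @staticmethod
    def _gather(x: np.ndarray, kernel: int, dilation: int) -> np.ndarray:
        n, h, w, c = x.shape
        pad = dilation * (kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        ii = np.arange(h)[:, None] + dilation * np.arange(kernel)[None, :]
        jj = np.arange(w)[:, None] + dilation * np.arange(kernel)[None, :]
        cols = xp[:, ii[:, None, :, None], jj[None, :, None, :], :]
        return cols.reshape(n * h * w, kernel * kernel * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = self._gather(x, self.kernel, self.dilation)
        y = cols @ self.weight.value + self.bias.value
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, h, w, c = xshape
        dyf = dy.reshape(-1, self.cout)
        self.weight.grad += cols.T @ dyf
        self.bias.grad += dyf.sum(axis=0)
        # dx = dy (*) flip(W)^T  — stride-1 / same-padding transpose conv
        wk = self.weight.value.reshape(self.kernel, self.kernel, self.cin, self.cout)
        wflip = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, self.cin)
        dcols = self._gather(dy, self.kernel, self.dilation)
        dx = dcols @ wflip
        return dx.reshape(n, h, w, c)


class Dense(Module):
    """Affine map over the last axis."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        w = np.zeros((cin, cout), dtype=np.float32) if zero_init else _he_init(rng, cin, (cin, cout))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.weight.grad += x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.bias.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.weight.value.T


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd, train, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, train, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        g = self.gamma.value * invstd
        if not train:
            return dy * g
        m = shape[0] * shape[1] * shape[2]
        dxhat = dy * self.gamma.value
        dx = (dxhat - dxhat.mean(axis=(0, 1, 2))
              - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)) / m) * invstd
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        neg = x <= 0
        self._y_neg = self.alpha * np.expm1(np.minimum(x, 0.0))
        self._neg = neg
        return np.where(neg, self._y_neg, x).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        grad = np.where(self._neg, self._y_neg + self.alpha, 1.0)
        return (dy * grad).astype(np.float32)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResBlock(Module):
    """Two [BatchNorm, activation, Conv] sub-layers with a skip connection.

    If the input/output channel counts differ, the skip path uses a
    1x1 projection convolution.
    """

    def __init__(self, cin: int, mid: int, cout: int, k1: int, k2: int,
                 dilation2: int = 1, act: str = "relu",
                 rng: np.random.Generator | None = None):
        act_cls = ReLU if act == "relu" else ELU
        self.body = Sequential(
            BatchNorm2d(cin), act_cls(), Conv2d(cin, mid, k1, rng=rng),
            BatchNorm2d(mid), act_cls(), Conv2d(mid, cout, k2, dilation=dilation2, rng=rng),
        )
        self.proj = Conv2d(cin, cout, 1, rng=rng) if cin != cout else None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.body.forward(x, train=train)
        skip = self.proj.forward(x, train=train) if self.proj is not None else x
        return y + skip

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.body.backward(dy)
        if self.proj is not None:
            dx = dx + self.proj.backward(dy)
        else:
            dx = dx + dy
        return dx
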