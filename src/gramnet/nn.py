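"""Minimal CPU neural-network engine used by the segmentation and
classification models in this package.

Layers operate on ``float32`` arrays in NCHW layout and implement explicit
forward/backward passes (verified against central finite differences in the
test suite).  Convolutions are stride-1 with odd kernels and 'same' padding,
realised as an im2col matrix product; the input gradient is computed as a
correlation of the output gradient with the channel-transposed, spatially
flipped kernel, which keeps the backward pass a matrix product as well.

Only what the models here need is provided: Conv2d, BatchNorm2d, ReLU,
MaxPool2 (ceil mode, saturating at 1x1), Upsample2, average pooling,
Linear, Sigmoid, and an Adam optimizer with decoupled-from-nothing plain
L2 weight decay (added to the gradient).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "Upsample2",
    "AvgPoolTo",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "he_init",
]


class Parameter:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.data.size)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Kaiming-normal initialization for ReLU networks."""
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Layer:
    """Base layer.  ``frozen`` layers skip parameter-gradient accumulation
    and (for BatchNorm) always use running statistics."""

    frozen: bool = False

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        raise NotImplementedError

    def madd(self, in_shape) -> int:
        """Multiply-add count for one forward pass at ``in_shape`` (C, H, W)."""
        return 0

    def out_shape(self, in_shape):
        return in_shape


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*kh*kw) patch matrix, 'same' zero padding."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    return np.ascontiguousarray(cols)


class Conv2d(Layer):
    """Stride-1 'same' convolution with odd kernel dimensions."""

    def __init__(self, in_channels: int, out_channels: int, kh: int, kw: int,
                 rng: np.random.Generator, bias: bool = True, name: str = ""):
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dimensions must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kh, self.kw = kh, kw
        fan_in = in_channels * kh * kw
        self.weight = Parameter(
            he_init(rng, (out_channels, in_channels, kh, kw), fan_in),
            name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_channels), name=f"{name}.bias") if bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        cols = _im2col(x, self.kh, self.kw)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        y = out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, (n, c, h, w))
        return np.ascontiguousarray(y)

    def backward(self, dy, need_dx=True):
        cols, (n, c, h, w) = self._cache
        dcols = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        if not self.frozen:
            self.weight.grad += (dcols.T @ cols).reshape(self.weight.data.shape)
            if self.bias is not None:
                self.bias.grad += dcols.sum(axis=0)
        if not need_dx:
            return None
        # dx = correlate(dy, flip(W).T) with 'same' padding
        wflip = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols_dy = _im2col(dy, self.kh, self.kw)
        dx = cols_dy @ wflip.reshape(self.in_channels, -1).T
        return np.ascontiguousarray(
            dx.reshape(n, h, w, self.in_channels).transpose(0, 3, 1, 2))

    def madd(self, in_shape):
        c, h, w = in_shape
        return h * w * self.in_channels * self.out_channels * self.kh * self.kw

    def out_shape(self, in_shape):
        _, h, w = in_shape
        return (self.out_channels, h, w)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = ""):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        use_batch_stats = train and not self.frozen
        if use_batch_stats:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std, use_batch_stats, x.shape)
        return y.astype(x.dtype)

    def backward(self, dy, need_dx=True):
        xhat, inv_std, used_batch_stats, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        if not self.frozen:
            self.gamma.grad += dgamma
            self.beta.grad += dbeta
        if not need_dx:
            return None
        g = self.gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if used_batch_stats:
            dx = g * (dy - dbeta[None, :, None, None] / m
                      - xhat * dgamma[None, :, None, None] / m)
        else:
            dx = g * dy
        return dx.astype(dy.dtype)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        return dy * self._mask


class Sigmoid(Layer):
    def __init__(self):
        self._out = None

    def forward(self, x, train=False):
        # numerically stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        if train:
            self._out = out
        return out

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        return dy * self._out * (1.0 - self._out)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, ceil mode (odd dims padded with -inf).

    A 1x1 input therefore maps to 1x1, so deep stacks saturate instead of
    erroring once the feature map cannot be halved further.
    """

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = (h + 1) // 2, (w + 1) // 2
        xp = x
        if h % 2 or w % 2:
            xp = np.pad(x, ((0, 0), (0, 0), (0, 2 * h2 - h), (0, 2 * w2 - w)),
                        constant_values=-np.inf)
        xr = xp.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h2, w2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w), (h2, w2))
        return np.ascontiguousarray(y)

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        idx, (n, c, h, w), (h2, w2) = self._cache
        flat = np.zeros((n, c, h2, w2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
        dxp = flat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dxp = dxp.reshape(n, c, 2 * h2, 2 * w2)
        return np.ascontiguousarray(dxp[:, :, :h, :w])

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, (h + 1) // 2, (w + 1) // 2)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, 2 * h, 2 * w)


class AvgPoolTo(Layer):
    """Average-pool spatial dims down to an integer-divisor target size."""

    def __init__(self, target_h: int, target_w: int):
        self.th, self.tw = target_h, target_w
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % self.th or w % self.tw:
            raise ValueError(f"cannot pool {h}x{w} to {self.th}x{self.tw}")
        kh, kw = h // self.th, w // self.tw
        y = x.reshape(n, c, self.th, kh, self.tw, kw).mean(axis=(3, 5))
        if train:
            self._cache = (kh, kw)
        return y

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        kh, kw = self._cache
        return dy.repeat(kh, axis=2).repeat(kw, axis=3) / (kh * kw)

    def out_shape(self, in_shape):
        c, _, _ = in_shape
        return (c, self.th, self.tw)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).astype(dy.dtype)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = ""):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(he_init(rng, (out_features, in_features), in_features),
                                name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_features), name=f"{name}.bias")
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy, need_dx=True):
        if not self.frozen:
            self.weight.grad += dy.T @ self._x
            self.bias.grad += dy.sum(axis=0)
        if not need_dx:
            return None
        return dy @ self.weight.data

    def madd(self, in_shape):
        return self.in_features * self.out_features


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    @property
    def frozen(self):
        return all(getattr(l, "frozen", False) for l in self.layers if l.parameters())

    @frozen.setter
    def frozen(self, value: bool):
        for l in self.layers:
            l.frozen = value

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy, need_dx=True):
        # a frozen prefix never needs dx once no trainable layer precedes it
        for i in range(len(self.layers) - 1, -1, -1):
            upstream_trainable = need_dx or any(
                not l.frozen for l in self.layers[:i] if l.parameters())
            dy = self.layers[i].backward(dy, need_dx=upstream_trainable)
            if dy is None and i > 0:
                return None
        return dy

    def madd(self, in_shape):
        total = 0
        for l in self.layers:
            total += l.madd(in_shape)
            in_shape = l.out_shape(in_shape)
        return total

    def out_shape(self, in_shape):
        for l in self.layers:
            in_shape = l.out_shape(in_shape)
        return in_shape


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of an (N, M) logit matrix."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with optional L2 weight decay added to the raw gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
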