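"""Minimal dense-prediction neural-network layers in pure numpy.

Implements exactly the building blocks the segmentation network needs —
3x3/1x1 convolution, batch normalization, parametric ReLU, 2x max pooling,
nearest-neighbour upsampling, channel concatenation — each with an explicit
backward pass, plus the Adam optimizer and a soft multi-class Dice loss.
All arrays are NCHW float64; gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padding convolution, stride 1, odd kernel size."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        std = np.sqrt(2.0 / (c_in * kernel * kernel))  # He initialization
        self.w = Param(rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    @staticmethod
    def _windows(x: np.ndarray, k: int) -> np.ndarray:
        pad = k // 2
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        return sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        win = self._windows(x, self.kernel)
        y = np.tensordot(win, self.w.value, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,O)
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win = self._windows(self._x, self.kernel)
        self.w.grad += np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        w_flip = self.w.value[:, :, ::-1, ::-1]
        win_dy = self._windows(dy, self.kernel)
        dx = np.tensordot(win_dy, w_flip, axes=([1, 4, 5], [0, 2, 3]))  # (N,H,W,C)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivstd[None, :, None, None]
        if train:
            self._cache = (xhat, ivstd, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivstd, m = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        # dx in terms of batch statistics (standard closed form)
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m) * ivstd[None, :, None, None]
        return dx


class PReLU(Layer):
    """Parametric rectified linear unit with one learnable slope per channel."""

    def __init__(self, channels: int, init_slope: float = 0.25):
        self.slope = Param(np.full(channels, init_slope))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.slope]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        neg = np.minimum(x, 0.0)
        return np.maximum(x, 0.0) + self.slope.value[None, :, None, None] * neg

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        neg = np.minimum(x, 0.0)
        self.slope.grad += (dy * neg).sum(axis=(0, 2, 3))
        return dy * np.where(x > 0, 1.0, self.slope.value[None, :, None, None])


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dice_loss_and_grad(
    logits: np.ndarray, target_onehot: np.ndarray, eps: float = 1e-6
) -> tuple[float, np.ndarray]:
    """Soft multi-class Dice loss and its gradient w.r.t. the logits.

    Loss = 1 - mean over samples and classes of
    ``(2 * sum(p_c t_c) + eps) / (sum(p_c) + sum(t_c) + eps)`` where ``p``
    is the per-pixel softmax of the logits.
    """
    p = softmax(logits, axis=1)
    n, c = logits.shape[:2]
    inter = (p * target_onehot).sum(axis=(2, 3))  # (N, C)
    psum = p.sum(axis=(2, 3))
    tsum = target_onehot.sum(axis=(2, 3))
    num = 2.0 * inter + eps
    den = psum + tsum + eps
    loss = float(1.0 - (num / den).mean())
    # dL/dp, then pull back through the softmax
    dnum = 2.0 * target_onehot
    dp = -(dnum * den[:, :, None, None] - num[:, :, None, None]) / (
        den[:, :, None, None] ** 2
    ) / (n * c)
    dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    return loss, dz
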