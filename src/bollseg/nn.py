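"""Minimal numpy layers with hand-written backprop for encoder-decoder nets.

Everything operates on float32 NCHW tensors.  Convolutions are expressed as
im2col gathers followed by a single BLAS matmul, which keeps desk-scale
training (64 x 64 tiles, tens of channels) fast enough on one CPU core.
Only the pieces an encoder-decoder segmentation net needs are implemented:

* ``Conv2d`` — 2-D convolution with odd kernel, dilation support, and
  "same" zero padding of ``dilation * (kernel - 1) / 2`` so spatial size is
  preserved at any dilation rate.
* ``BatchNorm2d`` — per-channel batch normalization with running statistics.
* ``ReLU``.
* ``MaxPool2d`` — 2 x 2, stride 2, returning argmax indices.
* ``MaxUnpool2d`` — scatters values back to the recorded argmax positions.
* ``softmax`` / ``cross_entropy`` on per-pixel class logits.
* ``Adam`` optimizer.

Layers cache what backward needs on forward; ``backward`` must be called
with the same shapes forward produced.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "MaxUnpool2d",
    "softmax",
    "cross_entropy",
    "Adam",
]

_F32 = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Conv2d:
    """Same-padded 2-D convolution, odd kernel, optional dilation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        self.pad = dilation * (kernel - 1) // 2
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, d, p = self.kernel, self.dilation, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, k * k, h, w), dtype=_F32)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, ki * k + kj] = xp[:, :, ki * d : ki * d + h, kj * d : kj * d + w]
        return cols.reshape(n, c * k * k, h * w)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        w2 = self.weight.value.reshape(self.out_channels, -1)
        out = np.matmul(w2, cols)  # (N, out, H*W)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        self._cols, self._xshape = cols, x.shape
        return out.reshape(n, self.out_channels, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = dout.shape
        k, d, p = self.kernel, self.dilation, self.pad
        g = dout.reshape(n, self.out_channels, h * w)
        self.weight.grad += np.einsum("nof,ncf->oc", g, self._cols).reshape(
            self.weight.value.shape
        )
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        w2 = self.weight.value.reshape(self.out_channels, -1)
        dcols = np.matmul(w2.T, g).reshape(n, self.in_channels, k * k, h, w)
        _, c, hh, ww = self._xshape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki * d : ki * d + h, kj * d : kj * d + w] += dcols[:, :, ki * k + kj]
        self._cols = None
        return dxp[:, :, p : p + hh, p : p + ww] if p else dxp


class BatchNorm2d:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

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
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return out.astype(_F32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        # standard batch-norm backward: couples every sample through mean/var
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        self._cache = None
        return dx.astype(_F32, copy=False)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(_F32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(_F32, copy=False)


class MaxPool2d:
    """2x2 max pooling with stride 2; records argmax for paired unpooling."""

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._in_shape = x.shape
        self._idx = idx
        return out.astype(_F32, copy=False), idx

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return unpool(dout, self._idx, self._in_shape)


def unpool(values: np.ndarray, idx: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Place each value at its recorded within-window argmax position."""
    n, c, h, w = out_shape
    win = np.zeros((n, c, h // 2, w // 2, 4), dtype=_F32)
    np.put_along_axis(win, idx[..., None], values[..., None].astype(_F32), axis=-1)
    return win.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class MaxUnpool2d:
    """Inverse of MaxPool2d given the recorded indices."""

    def forward(self, x: np.ndarray, idx: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._idx = idx
        return unpool(x, idx, (n, c, h * 2, w * 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        win = dout.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits.

    ``logits``: (N, K, H, W); ``labels``: (N, H, W) integer classes.
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    flat = p.transpose(0, 2, 3, 1).reshape(-1, k)
    lab = labels.reshape(-1)
    wts = np.ones(lab.size, dtype=_F32) if class_weights is None else np.asarray(
        class_weights, dtype=_F32
    )[lab]
    picked = np.clip(flat[np.arange(lab.size), lab], 1e-12, None)
    denom = wts.sum()
    loss = float(-(wts * np.log(picked)).sum() / denom)
    grad_flat = flat * wts[:, None]
    grad_flat[np.arange(lab.size), lab] -= wts
    grad = grad_flat.reshape(n, h, w, k).transpose(0, 3, 1, 2) / denom
    return loss, grad.astype(_F32, copy=False)


class Adam:
    """Adam with bias correction; default betas follow the training recipe."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.98,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
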