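"""Layer primitives. Convolutions use im2col/col2im so the inner loop is a
single BLAS matmul; transposed convolution is implemented as the exact
adjoint of the strided convolution (col2im of W^T x), which guarantees the
gradient pair (convT forward == conv backward-data) is consistent."""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = _out_size(h, k, stride, pad)
    wo = _out_size(w, k, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return windows.reshape(n, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back to (N,C,H,W)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        self.weight = Param(rng.normal(0.0, 0.02, size=(out_ch, in_ch, k, k)))
        self.bias = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        ho = _out_size(h, self.k, self.stride, self.pad)
        wo = _out_size(w, self.k, self.stride, self.pad)
        cols = _im2col(x, self.k, self.stride, self.pad)
        wm = self.weight.value.reshape(self.out_ch, -1)
        out = np.matmul(wm, cols) + self.bias.value[:, None]
        self._cache = (x.shape, cols)
        return out.reshape(n, self.out_ch, ho, wo)

    def backward(self, grad):
        x_shape, cols = self._cache
        n = grad.shape[0]
        g2 = grad.reshape(n, self.out_ch, -1)
        self.weight.grad += np.einsum("ncl,nkl->ck", g2, cols).reshape(self.weight.value.shape)
        self.bias.grad += g2.sum(axis=(0, 2))
        wm = self.weight.value.reshape(self.out_ch, -1)
        dcols = np.matmul(wm.T, g2)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution; forward is the adjoint of Conv2d."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        self.weight = Param(rng.normal(0.0, 0.02, size=(in_ch, out_ch, k, k)))
        self.bias = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        ho = (h - 1) * self.stride - 2 * self.pad + self.k
        wo = (w - 1) * self.stride - 2 * self.pad + self.k
        xf = x.reshape(n, self.in_ch, h * w)
        wm = self.weight.value.reshape(self.in_ch, -1)  # (Cin, Cout*k*k)
        cols = np.einsum("ik,nil->nkl", wm, xf)
        out = _col2im(cols, (n, self.out_ch, ho, wo), self.k, self.stride, self.pad)
        out += self.bias.value[None, :, None, None]
        self._cache = (x.shape, xf)
        return out

    def backward(self, grad):
        x_shape, xf = self._cache
        n = grad.shape[0]
        dcols = _im2col(grad, self.k, self.stride, self.pad)  # (N, Cout*k*k, H*W)
        wm = self.weight.value.reshape(self.in_ch, -1)
        self.weight.grad += np.einsum("nkl,nil->ik", dcols, xf).reshape(self.weight.value.shape)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        dxf = np.einsum("ik,nkl->nil", wm, dcols)
        return dxf.reshape(x_shape)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation over the spatial axes, with a
    learned affine transform. At batch size one this coincides with batch
    normalisation in training mode, which keeps inference deterministic
    without running statistics."""

    def __init__(self, ch: int, rng: np.random.Generator, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(rng.normal(1.0, 0.02, size=ch))
        self.beta = Param(np.zeros(ch))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        mean = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y * self._y)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout. Active only when ``train=True`` or when an explicit
    generator has been armed via ``set_rng`` (used for stochastic inference,
    where dropout realises the noise input of the translator)."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def set_rng(self, rng: np.random.Generator | None):
        self.rng = rng if rng is not None else self.rng

    def forward(self, x, train=False):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2, stride-2 max pooling. Ties share the incoming gradient equally."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        self._cache = (mask, counts, x.shape)
        return out

    def backward(self, grad):
        mask, counts, x_shape = self._cache
        g = grad[:, :, :, None, :, None] * mask / counts
        n, c, h, w = x_shape
        return g.reshape(n, c, h, w)


class Concat(Layer):
    """Channel-axis concatenation of two tensors (skip connections)."""

    def forward_pair(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._split = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, grad):
        return grad[:, : self._split], grad[:, self._split :]
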