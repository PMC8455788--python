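"""Minimal numpy CNN layers with hand-written backprop.

Backs the slice-wise inception U-Net.  Only what the segmenter needs is
implemented: 2D convolution (im2col), ReLU, inverted dropout, nearest
2x up-sampling, channel concatenation, softmax and the Adam optimizer.
Tensors are (N, C, H, W) float32; every layer exposes ``forward`` /
``backward`` and keeps its cache between the two calls.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2D",
    "ReLU",
    "Dropout",
    "Upsample2x",
    "softmax_channels",
    "Adam",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = xp.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (n, c, k, k, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(cols).reshape(n, c * k * k, oh * ow), (oh, ow, xp.shape)


def _col2im(dcols: np.ndarray, padded_shape, k: int, stride: int, pad: int):
    n, c, h, w = padded_shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    dx = np.zeros(padded_shape, dtype=np.float32)
    d6 = dcols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += d6[
                :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2D:
    """'same'-padded kxk convolution (pad = k//2), optional stride."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (oh, ow, padded_shape) = _im2col(x, self.k, self.stride, self.pad)
        wm = self.w.value.reshape(self.w.value.shape[0], -1)
        out = np.einsum("of,nfp->nop", wm, cols, optimize=True)
        out += self.b.value[None, :, None]
        self._cache = (cols, padded_shape, x.shape)
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, padded_shape, xshape = self._cache
        n, co, oh, ow = dout.shape
        d2 = dout.reshape(n, co, oh * ow)
        wm = self.w.value.reshape(co, -1)
        self.w.grad += np.einsum("nop,nfp->of", d2, cols, optimize=True).reshape(
            self.w.value.shape
        )
        self.b.grad += d2.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", wm, d2, optimize=True)
        return _col2im(dcols, padded_shape, self.k, self.stride, self.pad)


class ReLU:
    params: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout:
    """Inverted dropout; identity when ``train`` is False."""

    params: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train: bool):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Upsample2x:
    """Nearest-neighbour 2x spatial up-sampling."""

    params: list = []

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax over axis 1 of an (N, C, H, W) tensor."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
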