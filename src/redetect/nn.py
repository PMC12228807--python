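"""Minimal neural-network engine used by the denoising autoencoder.

Implements exactly the layer vocabulary the autoencoder needs — 3x3 "same"
convolutions (via im2col and BLAS matmul), 2x2 average pooling, nearest
upsampling, densely connected convolution blocks, fully connected layers,
batch normalization, ReLU/sigmoid — together with reverse-mode gradients and
an Adam optimizer. Everything is plain numpy: forward activations are cached
per layer, ``backward`` consumes the caches in reverse order.

Spatial tensors use channels-last (B, H, W, C) layout and convolutions run
as nine shift-accumulate BLAS matmuls on the contiguous input — no 9x patch
matrix is ever materialized, which is what makes the narrow layers of this
network fast on one CPU. The input gradient is the same shift-accumulate
correlation with the window-reversed, channel-transposed kernel, so one
routine serves both passes.

Float32 is the working precision; tests build float64 layers for
finite-difference gradient checks.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3x3",
    "AvgPool2",
    "Upsample2",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "Linear",
    "BatchNorm1d",
    "DenseBlock",
    "Sequential",
    "Adam",
]

class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_std(fan_in: int) -> float:
    return math.sqrt(2.0 / fan_in)


def _linear_std(fan_in: int) -> float:
    return math.sqrt(1.0 / fan_in)


def _conv9(x: np.ndarray, vstack: np.ndarray,
           bias: np.ndarray | None) -> np.ndarray:
    """3x3 same correlation by shift-accumulate.

    x (B,H,W,C), vstack (9, C, out_ch) where vstack[3*ky+kx] multiplies the
    input at spatial offset (ky-1, kx-1). Each window position is one BLAS
    matmul on the contiguous input followed by a shifted accumulation, so no
    9x patch matrix is ever materialized — substantially faster than im2col
    for the narrow layers this network uses.
    """
    b, h, w, c = x.shape
    cout = vstack.shape[2]
    xm = x.reshape(-1, c)
    acc = np.zeros((b, h + 2, w + 2, cout), dtype=x.dtype)
    for k in range(9):
        ky, kx = divmod(k, 3)
        y = (xm @ vstack[k]).reshape(b, h, w, cout)
        acc[:, 2 - ky:2 - ky + h, 2 - kx:2 - kx + w, :] += y
    out = acc[:, 1:1 + h, 1:1 + w, :].copy()
    if bias is not None:
        out += bias
    return out


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape preserving).

    The kernel is stored as (9, in_ch, out_ch), window-position major; the
    input gradient is the same shift-accumulate correlation with the
    window-reversed, channel-transposed stack.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 init: str = "he", dtype=np.float32) -> None:
        self.in_ch, self.out_ch = in_ch, out_ch
        std = _he_std(in_ch * 9) if init == "he" else _linear_std(in_ch * 9)
        w = rng.normal(0.0, std, size=(9, in_ch, out_ch)).astype(dtype)
        self.w = Param(w, "conv.w")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "conv.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return _conv9(x, self.w.value, self.b.value)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        b, h, w, _ = x.shape
        xm = x.reshape(-1, self.in_ch)
        gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (0, 0)))
        for k in range(9):
            ky, kx = divmod(k, 3)
            gv = np.ascontiguousarray(
                gp[:, 2 - ky:2 - ky + h, 2 - kx:2 - kx + w, :])
            self.w.grad[k] += xm.T @ gv.reshape(-1, self.out_ch)
        self.b.grad += g.reshape(-1, self.out_ch).sum(axis=0)
        wback = np.ascontiguousarray(self.w.value[::-1].transpose(0, 2, 1))
        self._x = None
        return _conv9(g, wback, None)


class AvgPool2(Layer):
    """2x2 average pooling with stride 2."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"AvgPool2 needs even spatial dims, got {h}x{w}")
        return x.reshape(b, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * g.dtype.type(0.25)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c = g.shape
        return g.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        # numerically stable logistic (no overflow for large |x|)
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        y = self._y
        self._y = None
        return g * y * (1.0 - y)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        self.shape = shape

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(g.shape[0], -1)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "he", dtype=np.float32) -> None:
        std = _he_std(n_in) if init == "he" else _linear_std(n_in)
        self.w = Param(rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype), "lin.w")
        self.b = Param(np.zeros(n_out, dtype=dtype), "lin.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        out = g @ self.w.value.T
        self._x = None
        return out


class BatchNorm1d(Layer):
    """Batch normalization over feature vectors.

    Batch statistics in training mode (with running-average tracking,
    momentum 0.1); running statistics in inference mode.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        self.gamma = Param(np.ones(n, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(n, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(n, dtype=dtype)
        self.running_var = np.ones(n, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
            self._inv = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu) * self._inv
            self._train = True
            return self.gamma.value * self._xhat + self.beta.value
        self._train = False
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        if not self._train:
            return g * self.gamma.value / np.sqrt(self.running_var + self.eps)
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        n = g.shape[0]
        dxhat = g * self.gamma.value
        dx = (inv / n) * (n * dxhat - dxhat.sum(axis=0)
                          - xhat * (dxhat * xhat).sum(axis=0))
        self._xhat = self._inv = None
        return dx.astype(g.dtype)


class DenseBlock(Layer):
    """Densely connected convolution block.

    ``n`` successive 3x3 convolutions, each producing ``k`` feature maps and
    receiving the channel-concatenation of the block input and every previous
    layer output; ReLU after each convolution. With ``k`` input channels the
    block maps k -> k, so it slots between the down/up-sampling convolutions
    without changing widths.
    """

    def __init__(self, k: int, n: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.k, self.n = k, n
        self.convs = [Conv3x3(k * (i + 1), k, rng, dtype=dtype) for i in range(n)]
        self.relus = [ReLU() for _ in range(n)]

    def params(self) -> list[Param]:
        return [p for c in self.convs for p in c.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        feats = [x]
        for conv, relu in zip(self.convs, self.relus):
            cat = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=-1)
            feats.append(relu.forward(conv.forward(cat, train), train))
        self._widths = [f.shape[-1] for f in feats[:-1]]
        return feats[-1]

    def backward(self, g: np.ndarray) -> np.ndarray:
        # gfeats[i] accumulates the gradient reaching feats[i]
        gfeats: list[np.ndarray | None] = [None] * (self.n + 1)
        gfeats[self.n] = g
        for i in range(self.n - 1, -1, -1):
            gcat = self.convs[i].backward(self.relus[i].backward(gfeats[i + 1]))
            # split along channels back onto feats[0..i]
            offset = 0
            for j in range(i + 1):
                cj = self.k if j else self._widths[0]
                piece = gcat[..., offset:offset + cj]
                gfeats[j] = piece.copy() if gfeats[j] is None else gfeats[j] + piece
                offset += cj
        return gfeats[0]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params: list[Param], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
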