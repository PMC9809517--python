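"""Minimal CPU neural-network engine used by the grading models.

A compact, dependency-free backend built on numpy: strided im2col
convolutions, pooling, dense layers, residual and dense-concat composite
blocks, explicit backpropagation, and an Adam optimizer with per-parameter
freeze flags.  It exists so that classifiers and segmenters in this package
train and introspect (activations + gradients at the last convolutional
layer, as saliency mapping requires) on a single CPU at test scale.

Layout convention is NCHW float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Flatten",
    "GlobalAvgPool",
    "BatchScale",
    "Dense",
    "Sequential",
    "Residual",
    "DenseBlock",
    "Adam",
    "softmax",
    "cross_entropy",
    "cross_entropy_grad",
    "sigmoid",
    "bce_loss",
]


class Param:
    """A learnable tensor with gradient buffer and a freeze flag."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = True
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: forward caches whatever backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution via im2col + BLAS matmul.

    ``counted`` distinguishes main-path convolutions (the ones the staged
    fine-tuning unfreeze rule indexes) from shortcut projections.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 counted: bool = True, name: str = "conv") -> None:
        rng = rng or np.random.default_rng(0)
        if pad is None:
            pad = k // 2
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.W = Param(_he_init(rng, (cout, cin * k * k), cin * k * k), name + ".W")
        self.b = Param(np.zeros(cout, dtype=np.float32), name + ".b")
        self.counted = counted
        self.name = name
        # caches for backward / saliency
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None
        self.out_cache: np.ndarray | None = None
        self.dout_cache: np.ndarray | None = None
        self.compute_param_grads = True

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        hp, wp = x.shape[2], x.shape[3]
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, c, ho, wo, k, k) -> (n*ho*wo, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.W.value.T + self.b.value
        out = out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        self._cols = cols
        self._xshape = (n, c, h, w, hp, wp, ho, wo)
        self.out_cache = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dout_cache = dout
        n, c, h, w, hp, wp, ho, wo = self._xshape
        k, s, p = self.k, self.stride, self.pad
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        dmat = np.ascontiguousarray(dmat, dtype=np.float32)
        if self.compute_param_grads and (self.W.trainable or self.b.trainable):
            self.W.grad += dmat.T @ self._cols
            self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ self.W.value  # (n*ho*wo, c*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2.  Odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : h2 * 2, : w2 * 2]
        self._inshape = (n, c, h, w)
        xr = x.reshape(n, c, h2, 2, w2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        h2, w2 = h // 2, w // 2
        d = self._mask * dout[:, :, :, None, :, None]
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, : h2 * 2, : w2 * 2] = d.reshape(n, c, h2 * 2, w2 * 2)
        return dx


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling (decoder path of the segmenter)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._inshape)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class CoordChannel(Layer):
    """Appends a fixed horizontal-coordinate ramp channel (-1 at the
    viewer-left edge, +1 at the viewer-right edge).  Gives a globally
    pooled classifier access to laterality, which plain convolutions
    cannot otherwise express on a whole-thorax input."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ramp = np.tile(np.linspace(-1.0, 1.0, w, dtype=np.float32), (h, 1))
        return np.concatenate([x, np.broadcast_to(ramp, (n, 1, h, w))], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout[:, :-1]


class BatchScale(Layer):
    """Fixed per-feature standardization, initialized from the first batch
    it sees and frozen thereafter (data-dependent init; no learned state).
    Conditions the classifier head on arbitrary backbone feature scales."""

    def __init__(self, eps: float = 1e-4) -> None:
        self.mean: np.ndarray | None = None
        self.scale: np.ndarray | None = None
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.mean is None:
            if x.shape[0] < 8:   # too few rows for stable statistics
                self._cur = None
                return x
            self.mean = x.mean(axis=0)
            self.scale = 1.0 / (x.std(axis=0) + self.eps)
        self._cur = self.scale
        return (x - self.mean) * self.scale

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._cur is None else dout * self._cur


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 name: str = "fc") -> None:
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, (cin, cout), cin), name + ".W")
        self.b = Param(np.zeros(cout, dtype=np.float32), name + ".b")
        self.compute_param_grads = True

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.compute_param_grads and (self.W.trainable or self.b.trainable):
            self.W.grad += self._x.T @ dout
            self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Residual(Layer):
    """out = body(x) + shortcut(x); identity shortcut when None."""

    def __init__(self, body: Sequential, shortcut: Layer | None = None) -> None:
        self.body = body
        self.shortcut = shortcut

    def params(self) -> list[Param]:
        ps = self.body.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = self.body.forward(x)
        s = x if self.shortcut is None else self.shortcut.forward(x)
        return b + s

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.body.backward(dout)
        if self.shortcut is None:
            dx = dx + dout
        else:
            dx = dx + self.shortcut.backward(dout)
        return dx


class DenseBlock(Layer):
    """Densely connected block: each sub-layer sees the concat of all
    previous feature maps and appends ``growth`` new channels."""

    def __init__(self, cin: int, n_layers: int, growth: int,
                 rng: np.random.Generator | None = None, name: str = "dense") -> None:
        self.sub: list[Sequential] = []
        c = cin
        for i in range(n_layers):
            self.sub.append(Sequential([
                ReLU(),
                Conv2d(c, growth * 2, k=1, rng=rng, name=f"{name}.{i}.pw"),
                ReLU(),
                Conv2d(growth * 2, growth, k=3, rng=rng, name=f"{name}.{i}.conv"),
            ]))
            c += growth
        self.cout = c

    def params(self) -> list[Param]:
        return [p for s in self.sub for p in s.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = [x]
        self._widths = [x.shape[1]]
        for s in self.sub:
            cat = np.concatenate(feats, axis=1)
            y = s.forward(cat)
            feats.append(y)
            self._widths.append(y.shape[1])
        return np.concatenate(feats, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # split the concat gradient back onto each produced feature map
        splits = np.cumsum(self._widths)[:-1]
        dfeats = list(np.split(dout, splits, axis=1))
        for idx in range(len(self.sub) - 1, -1, -1):
            dcat = self.sub[idx].backward(dfeats[idx + 1])
            # dcat covers concat(feats[:idx+1]); fold back
            sub_splits = np.cumsum(self._widths[: idx + 1])[:-1]
            parts = np.split(dcat, sub_splits, axis=1)
            for j, part in enumerate(parts):
                dfeats[j] = dfeats[j] + part
        return dfeats[0]


def iter_convs(layer: Layer, include_shortcut: bool = False):
    """Yield Conv2d layers in forward order."""
    if isinstance(layer, Conv2d):
        if layer.counted or include_shortcut:
            yield layer
    elif isinstance(layer, Sequential):
        for l in layer.layers:
            yield from iter_convs(l, include_shortcut)
    elif isinstance(layer, Residual):
        yield from iter_convs(layer.body, include_shortcut)
        if include_shortcut and layer.shortcut is not None:
            yield from iter_convs(layer.shortcut, include_shortcut)
    elif isinstance(layer, DenseBlock):
        for s in layer.sub:
            yield from iter_convs(s, include_shortcut)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = probs.shape[0]
    p = np.clip(probs[np.arange(n), labels], 1e-12, None)
    return float(-np.log(p).mean())


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = probs.shape[0]
    g = probs.copy()
    g[np.arange(n), labels] -= 1.0
    return g / n


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def bce_loss(p: np.ndarray, t: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


class Adam:
    """Adam with per-Param state; frozen params are skipped.

    ``weight_decay`` is decoupled (applied directly to the parameter,
    scaled by the learning rate) and only touches matrix/kernel
    parameters, never biases.  Besides regularizing, it shrinks the
    input-independent component of feature activations, which keeps
    gradient-weighted saliency maps concentrated on discriminative
    image regions."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.value.ndim >= 2:
                p.value -= self.lr * self.weight_decay * p.value

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
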