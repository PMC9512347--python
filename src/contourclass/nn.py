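"""Minimal neural-network core: layers, weighted cross-entropy, SGD.

Implemented directly on numpy so the whole pipeline is deterministic,
dependency-light and CPU-friendly at phantom scale.  The pieces are the
usual ones — affine layers, 3x3 strided convolutions (im2col + GEMM),
ReLU, inverted dropout, average pooling — wired together by the classifier
module.  All randomness (init, dropout, shuffling) flows from explicit
``numpy.random.Generator`` streams.

Shapes follow the torch convention: images are (B, C, H, W), features
(B, F).  ``forward(x, train=...)`` caches what ``backward(dout)`` needs;
a backward call must follow its forward call.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Module):
    """Affine layer with He-normal init (bias zero)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = Parameter(rng.normal(0.0, std, size=(n_out, n_in)).astype(np.float64))
        self.b = Parameter(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    @property
    def n_params(self) -> int:
        return self.W.value.size + self.b.value.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = 1.0
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    cols = np.empty((B, C, k, k, Ho, Wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
    return cols.reshape(B, C * k * k, Ho * Wo), (Ho, Wo)


class Conv2d(Module):
    """3x3-style convolution via im2col + GEMM."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 3,
        stride: int = 1,
        pad: int = 1,
    ):
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)
        self.W = Parameter(rng.normal(0.0, std, size=(c_out, fan_in)))
        self.b = Parameter(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._xshape = x.shape
        cols, (Ho, Wo) = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        out = np.einsum("of,bfl->bol", self.W.value, cols, optimize=True)
        out += self.b.value[None, :, None]
        return out.reshape(x.shape[0], self.c_out, Ho, Wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, _, Ho, Wo = dout.shape
        dflat = dout.reshape(B, self.c_out, Ho * Wo)
        self.W.grad += np.einsum("bol,bfl->of", dflat, self._cols, optimize=True)
        self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,bol->bfl", self.W.value, dflat, optimize=True)

        k, stride, pad = self.k, self.stride, self.pad
        _, C, H, W = self._xshape
        dcols = dcols.reshape(B, C, k, k, Ho, Wo)
        dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += dcols[
                    :, :, i, j
                ]
        return dxp[:, :, pad : pad + H, pad : pad + W]


class AvgPool2d(Module):
    """Non-overlapping average pooling by an integer factor."""

    def __init__(self, factor: int):
        self.f = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.f == 1:
            return x
        B, C, H, W = x.shape
        f = self.f
        if H % f or W % f:
            raise ValueError(f"spatial dims {(H, W)} not divisible by pool factor {f}")
        self._shape = x.shape
        return x.reshape(B, C, H // f, f, W // f, f).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.f == 1:
            return dout
        B, C, H, W = self._shape
        f = self.f
        return np.repeat(np.repeat(dout, f, axis=2), f, axis=3) / (f * f)


class GlobalMomentPool(Module):
    """Global pooling that keeps coarse location: per channel, the mean
    activation plus its first spatial moments along x and y (coordinates
    normalized to [-1, 1]).  Output is (B, 3C), grid-size agnostic.

    A plain global average is fully translation-invariant and therefore
    blind to laterality; the first moments restore the frame-position
    information that deep full-frame backbones retain through border
    effects."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        self._shape = x.shape
        self._gx = np.linspace(-1.0, 1.0, W)[None, None, None, :]
        self._gy = np.linspace(-1.0, 1.0, H)[None, None, :, None]
        m0 = x.mean(axis=(2, 3))
        mx = (x * self._gx).mean(axis=(2, 3))
        my = (x * self._gy).mean(axis=(2, 3))
        return np.concatenate([m0, mx, my], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        d0, dx, dy = dout[:, :C], dout[:, C : 2 * C], dout[:, 2 * C :]
        scale = 1.0 / (H * W)
        out = np.full(self._shape, 0.0)
        out += d0[:, :, None, None] * scale
        out += dx[:, :, None, None] * (self._gx * scale)
        out += dy[:, :, None, None] * (self._gy * scale)
        return out


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (H * W) + np.zeros(
            self._shape
        )


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy, averaged over the batch.

    ``loss = mean_i w[y_i] * (-log p_i[y_i])`` — each sample's term scales
    linearly with its class weight, so doubling a class's weight doubles
    that class's contribution to the batch loss.  Returns (loss, dlogits).
    """
    B = logits.shape[0]
    p = softmax(logits)
    w = (
        np.ones(B)
        if class_weights is None
        else np.asarray(class_weights, dtype=float)[labels]
    )
    nll = -np.log(np.clip(p[np.arange(B), labels], 1e-12, None))
    loss = float((w * nll).mean())
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits *= (w / B)[:, None]
    return loss, dlogits


class SGD:
    """Plain stochastic gradient descent with optional L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            p.value -= self.lr * g

    def state_dict(self) -> dict:
        return {"lr": self.lr, "weight_decay": self.weight_decay}
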