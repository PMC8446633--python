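"""A compact numpy convolutional-network engine.

Provides exactly the pieces the stomata detector and the cell segmenter
need: 2-D convolutions (im2col + BLAS matmul, explicit backward pass), ReLU,
2x2 max pooling, nearest-neighbour upsampling, channel concatenation,
residual blocks, Kaiming-normal initialization and momentum SGD.  Everything
runs in float32 and is fully deterministic given a seeded generator, which is
what makes the training contracts ("same seed twice -> identical final
loss") exactly testable.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "ConvBlock",
    "ResidualBlock",
    "SGD",
    "sigmoid",
    "bce_with_logits",
    "softmax_cross_entropy",
]


def kaiming_normal(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d:
    """k x k convolution with 'same' padding by default (stride 1 or 2)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = kaiming_normal(rng, (cout, cin * k * k), cin * k * k)
        self.b = np.zeros(cout, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: Optional[np.ndarray] = None
        self._xshape: Optional[Tuple[int, ...]] = None

    def params(self) -> List[tuple]:
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, oh, ow, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, oh * ow, c * k * k
        )
        out = cols @ self.W.T + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, s, p = self.k, self.stride, self.pad
        _, _, oh, ow = dout.shape
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n, oh * ow, self.cout)
        cols = self._cols
        self.dW += np.einsum("nij,nik->jk", d2, cols, optimize=True)
        self.db += d2.sum(axis=(0, 1))
        dcols = d2 @ self.W  # (n, oh*ow, c*k*k)
        dcols = dcols.reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU:
    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2 (even input sizes only)."""

    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = v.max(axis=(3, 5))
        if train:
            self._mask = v == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = self._mask * dout[:, :, :, None, :, None]
        # ties route gradient to every maximum; split evenly for symmetry
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        return (d / counts).reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """Two 3x3 conv + ReLU pairs (the standard encoder/decoder unit)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.layers = [Conv2d(cin, cout, 3, rng=rng), ReLU(), Conv2d(cout, cout, 3, rng=rng), ReLU()]

    def params(self) -> list:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ResidualBlock:
    """y = relu(x + conv(relu(conv(x)))), channel-preserving.

    The second conv starts at zero so the block is the identity at
    initialization; without this, stacked unnormalized residual branches can
    blow up activations for unlucky seeds.
    """

    def __init__(self, ch: int, rng: np.random.Generator) -> None:
        self.c1 = Conv2d(ch, ch, 3, rng=rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(ch, ch, 3, rng=rng)
        self.c2.W[...] = 0.0
        self.r2 = ReLU()

    def params(self) -> list:
        return self.c1.params() + self.c2.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = self.c2.forward(self.r1.forward(self.c1.forward(x, train), train), train)
        return self.r2.forward(x + y, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.r2.backward(dout)
        dy = self.c1.backward(self.r1.backward(self.c2.backward(d)))
        return d + dy


class SGD:
    """Momentum SGD over a list of (param, grad) pairs.

    ``clip_norm`` rescales the global gradient norm when it exceeds the
    bound; rare early steps can otherwise explode a randomly initialized
    residual backbone.
    """

    def __init__(
        self,
        params: Sequence[tuple],
        lr: float,
        momentum: float = 0.9,
        clip_norm: Optional[float] = None,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for _, g in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for _, g in self.params:
                    g *= scale
        for (p, g), v in zip(self.params, self.v):
            v *= self.momentum
            v -= self.lr * g
            p += v


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    n = z.size
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / n
    return loss, dz.astype(np.float32)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Row-wise softmax cross-entropy.

    ``logits`` is (n, classes), ``targets`` integer labels (n,).  Returns the
    per-row losses and dloss/dlogits (not normalized by n, so the caller
    controls the averaging convention).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    losses = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None))
    dz = p.copy()
    dz[np.arange(n), targets] -= 1.0
    return losses, dz.astype(np.float32)
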