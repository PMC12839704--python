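"""A compact convolutional network implemented directly on numpy.

Forward and backward passes are written out explicitly (convolutions as a
sum of strided tensor contractions over kernel offsets), which keeps the
whole classifier dependency-free and makes the exact gradients needed for
class-activation mapping available without an autograd framework. The
architecture is deliberately small — four strided conv/ReLU blocks,
concatenated global average+max pooling and a 2-class linear head — sized
for a few hundred training images on a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "GlobalAvgPool", "Linear", "ConvNet", "Adam",
           "softmax", "softmax_cross_entropy"]


class Conv2d:
    """2-D convolution (cross-correlation) with stride and zero padding."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        ho, wo = self.out_shape(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros(
            (n, ho, wo, self.W.shape[0]), dtype=np.promote_types(x.dtype, self.W.dtype)
        )
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s]
                # (n,ci,ho,wo) x (co,ci) -> (n,ho,wo,co)
                out += np.tensordot(xs, self.W[:, :, ki, kj], axes=([1], [1]))
        out += self.b
        self._cache = xp
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._cache
        n, _, hp, wp = xp.shape
        k, s = self.k, self.stride
        ho, wo = dout.shape[2], dout.shape[3]
        self.db[:] = dout.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        self.dW[:] = 0
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s]
                # (n,co,ho,wo) x (n,ci,ho,wo) -> (co,ci)
                self.dW[:, :, ki, kj] = np.tensordot(
                    dout, xs, axes=([0, 2, 3], [0, 2, 3])
                )
                # (n,co,ho,wo) x (co,ci) -> (n,ho,wo,ci)
                contrib = np.tensordot(dout, self.W[:, :, ki, kj], axes=([1], [0]))
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                    contrib.transpose(0, 3, 1, 2)
                )
        p = self.pad
        return dxp[:, :, p : hp - p, p : wp - p] if p else dxp

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class GlobalAvgPool:
    """(n, c, h, w) -> (n, c), averaging over the spatial grid."""

    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)

    def params(self):
        return []


class GlobalMaxPool:
    """(n, c, h, w) -> (n, c); gradient routes to each channel's argmax."""

    def __init__(self):
        self._x = None

    def forward(self, x):
        self._x = x
        return x.max(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._x.shape
        flat = self._x.reshape(n, c, h * w)
        arg = flat.argmax(axis=2)
        dflat = np.zeros_like(flat)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dflat[ni, ci, arg] = dout
        return dflat.reshape(self._x.shape)

    def params(self):
        return []


class AvgMaxPool:
    """Concatenated global average and max pooling: (n, c, h, w) -> (n, 2c).

    The average path summarizes curve-wide shape (submaximal effort,
    early termination); the max path detects localized anomalies (a cough
    spike) that a plain average would dilute over the feature grid.
    """

    def __init__(self):
        self.avg = GlobalAvgPool()
        self.max = GlobalMaxPool()

    def forward(self, x):
        return np.concatenate([self.avg.forward(x), self.max.forward(x)], axis=1)

    def backward(self, dout):
        c = dout.shape[1] // 2
        return self.avg.backward(dout[:, :c]) + self.max.backward(dout[:, c:])

    def params(self):
        return []


class Linear:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), (nout, nin)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[:] = dout.T @ self._x
        self.db[:] = dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class ConvNet:
    """Conv-ReLU ×4 → global avg+max pool → 2-class linear head.

    Input is a single-channel image batch (n, 1, H, W); the network is
    size-agnostic thanks to the global pooling, with 224 × 224 the
    intended operating point (feature grid 14 × 14 there).
    """

    def __init__(self, rng: np.random.Generator | None = None, n_classes: int = 2):
        rng = rng or np.random.default_rng(0)
        self.blocks = [
            Conv2d(1, 8, 5, stride=2, pad=2, rng=rng), ReLU(),
            Conv2d(8, 16, 3, stride=2, pad=1, rng=rng), ReLU(),
            Conv2d(16, 32, 3, stride=2, pad=1, rng=rng), ReLU(),
            Conv2d(32, 32, 3, stride=2, pad=1, rng=rng), ReLU(),
        ]
        self.pool = AvgMaxPool()
        self.head = Linear(64, n_classes, rng=rng)
        self._features = None

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.blocks:
            x = layer.forward(x)
        self._features = x  # last conv block activations (post-ReLU)
        return self.head.forward(self.pool.forward(x))

    @property
    def features(self) -> np.ndarray:
        """Activations of the last convolutional block from the last forward."""
        return self._features

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.backward_to_features(dlogits)
        for layer in reversed(self.blocks):
            d = layer.backward(d)
        return d

    def backward_to_features(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of the loss/score w.r.t. the last conv activations."""
        return self.pool.backward(self.head.backward(dlogits))

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        return [*self.blocks, self.pool, self.head]

    def param_triples(self):
        out = []
        for i, layer in enumerate(self._layers()):
            for name, p, g in layer.params():
                out.append((f"layer{i}.{name}", p, g))
        return out

    def get_params(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.param_triples()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.param_triples():
            p[...] = params[name]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


class Adam:
    """Adam optimizer over a network's parameter triples."""

    def __init__(self, net: ConvNet, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in net.param_triples()}
        self.v = {name: np.zeros_like(p) for name, p, _ in net.param_triples()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for name, p, g in self.net.param_triples():
            m = self.m[name]
            v = self.v[name]
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
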