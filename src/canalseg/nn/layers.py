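"""Layers with explicit forward/backward passes, NHWC float32 tensors.

Channels-last layout keeps the channel dimension contiguous, so a k x k
convolution runs as k^2 shifted GEMMs (one per kernel offset) with no
im2col gather; the input gradient and weight gradient reuse the same
shifted views.  Layers cache what backward needs on
``forward(..., train=True)`` and accumulate parameter gradients until
the optimiser clears them.
"""

from __future__ import annotations

import numpy as np

#: Global compute dtype.  float32 for production; tests may switch to
#: float64 for tight numerical-gradient verification.
DTYPE = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' padding by default (k odd)."""

    def __init__(self, cin: int, cout: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        self.k = k
        self.pad = k // 2 if pad is None else pad
        self.cin, self.cout = cin, cout
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialisation for ReLU nets
        self.W = Param(rng.normal(0.0, scale, size=(k, k, cin, cout)))
        self.b = Param(np.zeros(cout))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        if train:
            self._xp = xp
            self._in_shape = x.shape
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        out = np.empty((n * ho * wo, self.cout), dtype=xp.dtype)
        out[:] = self.b.value
        for i in range(k):
            for j in range(k):
                xv = np.ascontiguousarray(xp[:, i:i + ho, j:j + wo, :]).reshape(-1, self.cin)
                out += xv @ self.W.value[i, j]
        return out.reshape(n, ho, wo, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, h, w, _ = self._in_shape
        p, k = self.pad, self.k
        ho, wo = dout.shape[1], dout.shape[2]
        dr = dout.reshape(-1, self.cout)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xv = np.ascontiguousarray(xp[:, i:i + ho, j:j + wo, :]).reshape(-1, self.cin)
                self.W.grad[i, j] += xv.T @ dr
                dxp[:, i:i + ho, j:j + wo, :] += (dr @ self.W.value[i, j].T).reshape(n, ho, wo, self.cin)
        self.b.grad += dout.sum(axis=(0, 1, 2))
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, scale, size=(cin, 4 * cout)))
        self.b = Param(np.zeros(cout))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if train:
            self._x2 = x.reshape(-1, c)
            self._in_shape = x.shape
        t = (x.reshape(-1, c) @ self.W.value).reshape(n, h, w, 2, 2, self.cout)
        out = t.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.cout)
        return out + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        d6 = dout.reshape(n, h, 2, w, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        dr = np.ascontiguousarray(d6).reshape(-1, 4 * self.cout)
        self.W.grad += self._x2.T @ dr
        self.b.grad += dout.sum(axis=(0, 1, 2))
        return (dr @ self.W.value.T).reshape(n, h, w, c)


class Upsample2(Layer):
    """Fixed nearest-neighbour x2 upsampling (no parameters)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dout.shape
        return dout.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first
    of the four positions in (top-left, top-right, bottom-left,
    bottom-right) order."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        quads = (x[:, ::2, ::2], x[:, ::2, 1::2], x[:, 1::2, ::2], x[:, 1::2, 1::2])
        out = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        if train:
            self._quads_eq = []
            taken = np.zeros(out.shape, dtype=bool)
            for q in quads:
                m = (q == out) & ~taken
                taken |= m
                self._quads_eq.append(m)
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dout.dtype)
        views = (dx[:, ::2, ::2], dx[:, ::2, 1::2], dx[:, 1::2, ::2], dx[:, 1::2, 1::2])
        for v, m in zip(views, self._quads_eq):
            v += dout * m
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
            inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
            xhat = (x - mean) * inv
            self._xhat, self._inv = xhat, inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv
        return (self.gamma.value * xhat + self.beta.value).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma.value
        mean_dxhat = dxhat.mean(axis=(0, 1, 2))
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 1, 2))
        dx = inv * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        return dx.astype(DTYPE)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = -1) -> np.ndarray:
    """Gradient through softmax given dL/dprobs."""
    inner = (dprobs * probs).sum(axis=axis, keepdims=True)
    return probs * (dprobs - inner)


class Adam:
    """Adam optimiser over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
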