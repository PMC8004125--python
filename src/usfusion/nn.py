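"""Minimal numpy neural-network layers.

A convolutional layer computes ``X_k^m = sigma(W_k^m X^{m-1} + b_k^m)``;
here convolutions are evaluated by an im2col rearrangement followed by a
single matrix product, so both the forward pass of large frozen
architectures and the forward/backward pass of the small trainable
branch run on BLAS.  Arrays are NCHW ``float32``; all parameter
initialization draws from an explicit ``numpy.random.Generator``, so a
fixed seed gives bitwise-reproducible training on one platform.

Only what the package needs is implemented: Conv2D (He-initialized,
zero padding), ReLU, 2x2 max pooling, global average pooling, channel
instance normalization (keeps activations bounded through deep untrained
stacks), flatten, dense, and a softmax cross-entropy loss with an SGD
momentum optimizer.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# im2col plumbing

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]        # n,c,oh,ow,kh,kw
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int,
            stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                dcols[:, :, i, j]
    return dx[:, :, pad:pad + h, pad:pad + w] if pad else dx


# ---------------------------------------------------------------------------
# Layers

class Layer:
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_grads(self):
        return []


class Conv2D(Layer):
    trainable = True

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, fan_in))
                  * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(DTYPE, copy=False)
        cols, oh, ow = _im2col(x, self.k, self.k, self.stride, self.pad)
        out = np.einsum("of,nfp->nop", self.W, cols, optimize=True)
        out += self.b[None, :, None]
        self._cache = (x.shape, cols)
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n = grad.shape[0]
        g = grad.reshape(n, grad.shape[1], -1)
        self.dW[...] = np.einsum("nop,nfp->of", g, cols, optimize=True)
        self.db[...] = g.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.W, g, optimize=True)
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/cols are dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h - h % 2, w - w % 2
        self._in_shape = x.shape
        v = x[:, :, :h2, :w2].reshape(n, c, h2 // 2, 2, w2 // 2, 2)
        out = v.max(axis=(3, 5))
        mask = (v == out[:, :, :, None, :, None])
        # break ties deterministically: keep only the first maximum
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 // 2,
                                                        w2 // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = ((flat & first)
                      .reshape(n, c, h2 // 2, w2 // 2, 2, 2)
                      .transpose(0, 1, 2, 4, 3, 5))
        return out

    def backward(self, grad):
        n, c, h, w = self._in_shape
        h2, w2 = h - h % 2, w - w % 2
        dv = self._mask * grad[:, :, :, None, :, None]
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :, :h2, :w2] = dv.reshape(n, c, h2, w2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._in_shape).astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    trainable = True

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((d_in, d_out))
                  * np.sqrt(2.0 / d_in)).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x.astype(DTYPE, copy=False)
        return self._x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Sequential:
    """Ordered named layers with an optional tap point."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers

    def forward(self, x: np.ndarray, tap: str | None = None):
        tap_out = None
        for name, layer in self.layers:
            x = layer.forward(x)
            if name == tap:
                tap_out = x.reshape(x.shape[0], -1).copy()
        return (x, tap_out) if tap is not None else x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params_grads(self):
        out = []
        for _, layer in self.layers:
            out.extend(layer.params_grads())
        return out


# ---------------------------------------------------------------------------
# Loss and optimizer

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-30)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(DTYPE)


class SGDMomentum:
    """Classic momentum: v <- mu*v - lr*g; p <- p + v."""

    def __init__(self, params_grads, learning_rate: float = 2e-4,
                 momentum: float = 0.1):
        self.lr = learning_rate
        self.mu = momentum
        self._pg = params_grads
        self._v = [np.zeros_like(p) for p, _ in params_grads]

    def step(self) -> None:
        for v, (p, g) in zip(self._v, self._pg):
            v *= self.mu
            v -= self.lr * g
            p += v


# ---------------------------------------------------------------------------
# Forward-only functional ops (frozen large architectures)

class FrozenConv:
    """Stateless randomly-initialized convolution for shape-contract nets."""

    def __init__(self, c_in, c_out, k, rng, stride=1, pad=None):
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, fan_in))
                  * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)

    def __call__(self, x):
        cols, oh, ow = _im2col(x.astype(DTYPE, copy=False),
                               self.k, self.k, self.stride, self.pad)
        out = np.einsum("of,nfp->nop", self.W, cols, optimize=True)
        out += self.b[None, :, None]
        return out.reshape(x.shape[0], -1, oh, ow)


def relu(x):
    return np.maximum(x, 0.0)


def maxpool2(x):
    n, c, h, w = x.shape
    h2, w2 = h - h % 2, w - w % 2
    return x[:, :, :h2, :w2].reshape(n, c, h2 // 2, 2, w2 // 2, 2).max(axis=(3, 5))


def avgpool2(x):
    n, c, h, w = x.shape
    h2, w2 = h - h % 2, w - w % 2
    return x[:, :, :h2, :w2].reshape(n, c, h2 // 2, 2, w2 // 2, 2).mean(axis=(3, 5))


def global_avgpool(x):
    return x.mean(axis=(2, 3))


def channel_norm(x, eps: float = 1e-5):
    """Per-image, per-channel standardization (inference-time stabilizer)."""
    mu = x.mean(axis=(2, 3), keepdims=True)
    sd = x.std(axis=(2, 3), keepdims=True)
    return (x - mu) / (sd + eps)
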