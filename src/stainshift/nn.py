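"""Minimal convolutional-network toolkit (numpy, manual backprop).

Functional layers: ``forward`` returns ``(output, cache)``, ``backward``
consumes ``(cache, grad_output)``, accumulates parameter gradients in
place and returns the input gradient.  This lets one layer instance be
applied several times inside a single step (needed by the
cycle-consistent normalizer, whose generators run twice per step).

Tensors are (N, H, W, C) float32 — channels-last keeps the im2col
buffer contiguous so convolutions reduce to one BLAS matmul each way.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    params: list[Param]

    def __init__(self):
        self.params = []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) convolution via im2col; weight layout (F, C, k, k)."""

    def __init__(self, c_in, c_out, k=3, stride=1, pad=1, rng=None, weight_scale=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = weight_scale
        if scale is None:
            scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        w = (
            rng.normal(0.0, scale, size=(c_out, c_in, k, k))
            if scale > 0
            else np.zeros((c_out, c_in, k, k))
        )
        self.w = Param(np.asarray(w))
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, pad
        self.params = [self.w, self.b]

    def _wmat(self):
        # im2col feature order is (C, kh, kw); match it
        return self.w.value.transpose(1, 2, 3, 0).reshape(-1, self.w.value.shape[0])

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        k, s, p = self.k, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (N, Ho, Wo, C, kh, kw) -> contiguous (N*Ho*Wo, kh*kw*C)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, -1
        )
        # cols feature order is (kh, kw, C) after the transpose above
        wmat = self.w.value.transpose(2, 3, 1, 0).reshape(-1, self.w.value.shape[0])
        out = cols @ wmat + self.b.value
        out = out.reshape(n, ho, wo, -1)
        return out, ((n, h, w, c), cols if train else None)

    def backward(self, cache, grad, need_input: bool = True):
        (n, h, w, c), cols = cache
        k, s, p = self.k, self.stride, self.pad
        ho, wo = grad.shape[1], grad.shape[2]
        f = grad.shape[3]
        gmat = grad.reshape(n * ho * wo, f).astype(np.float32)
        dw = (cols.T @ gmat).reshape(k, k, c, f).transpose(3, 2, 0, 1)
        self.w.grad += dw
        self.b.grad += gmat.sum(axis=0)
        if not need_input:
            return None
        if s == 1:
            # dx is the full correlation of grad with the flipped kernel
            q = k - 1 - p
            gp = np.pad(grad, ((0, 0), (q, q), (q, q), (0, 0))).astype(np.float32)
            gwin = sliding_window_view(gp, (k, k), axis=(1, 2))
            gcols = np.ascontiguousarray(gwin.transpose(0, 1, 2, 4, 5, 3)).reshape(
                n * h * w, -1
            )
            # flipped kernel, (kh, kw, F) -> C feature order
            wflip = self.w.value[:, :, ::-1, ::-1].transpose(2, 3, 0, 1).reshape(-1, c)
            return (gcols @ wflip).reshape(n, h, w, c)
        wmat = self.w.value.transpose(2, 3, 1, 0).reshape(-1, f)
        dcols = (gmat @ wmat.T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + s * ho : s, dj : dj + s * wo : s, :] += dcols[
                    :, :, :, di, dj, :
                ]
        if p:
            return dxp[:, p : p + h, p : p + w, :]
        return dxp


class ReLU(Layer):
    def forward(self, x, train=True):
        return np.maximum(x, 0.0), (x > 0)

    def backward(self, cache, grad):
        return grad * cache


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        return np.where(x > 0, x, self.slope * x), (x > 0)

    def backward(self, cache, grad):
        return np.where(cache, grad, self.slope * grad)


class InstanceNorm(Layer):
    """Per-sample, per-channel spatial normalization with learned affine."""

    def __init__(self, channels, eps=1e-5):
        super().__init__()
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self.params = [self.gamma, self.beta]

    def forward(self, x, train=True):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        out = self.gamma.value * xhat + self.beta.value
        return out.astype(np.float32), (xhat, inv)

    def backward(self, cache, grad):
        xhat, inv = cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.value
        m = xhat.shape[1] * xhat.shape[2]
        g_sum = g.sum(axis=(1, 2), keepdims=True)
        g_dot = (g * xhat).sum(axis=(1, 2), keepdims=True)
        return (inv * (g - g_sum / m - xhat * g_dot / m)).astype(np.float32)


class AvgPool2(Layer):
    def forward(self, x, train=True):
        n, h, w, c = x.shape
        out = x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))
        return out, x.shape

    def backward(self, cache, grad):
        n, h, w, c = cache
        g = grad[:, :, None, :, None, :] / 4.0
        return np.broadcast_to(g, (n, h // 2, 2, w // 2, 2, c)).reshape(n, h, w, c)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), x.shape

    def backward(self, cache, grad):
        n, h, w, c = cache
        return grad.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        return x.mean(axis=(1, 2)), x.shape

    def backward(self, cache, grad):
        n, h, w, c = cache
        g = grad[:, None, None, :] / (h * w)
        return np.broadcast_to(g, cache).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in, d_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0, np.sqrt(1.0 / d_in), size=(d_out, d_in)))
        self.b = Param(np.zeros(d_out))
        self.params = [self.w, self.b]

    def forward(self, x, train=True):
        return x @ self.w.value.T + self.b.value, x

    def backward(self, cache, grad):
        self.w.grad += grad.T @ cache
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class Sequential(Layer):
    def __init__(self, *layers, input_grad: bool = True):
        super().__init__()
        self.layers = list(layers)
        self.params = [p for layer in layers for p in layer.params]
        self.input_grad = input_grad

    def forward(self, x, train=True):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, train=train)
            caches.append(cache)
        return x, caches

    def backward(self, caches, grad):
        first = self.layers[0]
        for layer, cache in zip(reversed(self.layers[1:]), reversed(caches[1:])):
            grad = layer.backward(cache, grad)
        if not self.input_grad and isinstance(first, Conv2d):
            return first.backward(caches[0], grad, need_input=False)
        return first.backward(caches[0], grad)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def load_state(self, arrays) -> None:
        for p, a in zip(self.params, arrays):
            p.value[...] = a


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m[...] = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v[...] = self.b2 * p.v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    p = sigmoid(z)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return loss, ((p - y) / z.size).astype(np.float32)
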