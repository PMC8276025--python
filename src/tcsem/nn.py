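"""Minimal functional neural-network layers with hand-written gradients.

Layers are parameter containers; ``forward`` returns ``(output, cache)`` and
``backward(cache, grad_out)`` returns the input gradient while accumulating
parameter gradients in place.  Because forward calls are side-effect free,
one layer instance can be applied at every step of an unrolled recurrence
(weight sharing across time) and back-propagation-through-time is just the
reverse sequence of ``backward`` calls.

All tensors are ``(N, C, H, W)`` arrays.  float32 is the working precision;
float64 is supported so gradients can be checked against finite differences.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import ConfigurationError


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter bookkeeping only; subclasses are functional."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Conv2d(Module):
    """Same-padded 2-D convolution with He fan-in initialization."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, *,
                 rng: np.random.Generator, name: str = "conv",
                 dtype=np.float32, zero_init: bool = False):
        if k % 2 != 1:
            raise ConfigurationError(f"kernel size must be odd, got {k}")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = math.sqrt(2.0 / (c_in * k * k))
        w = np.zeros((c_out, c_in, k, k)) if zero_init else rng.normal(
            0.0, std, size=(c_out, c_in, k, k))
        self.w = Param(w.astype(dtype), name + ".w")
        self.b = Param(np.zeros(c_out, dtype=dtype), name + ".b")

    def _wmat(self) -> np.ndarray:
        # (c_out, k*k*c_in) with taps ordered (i, j, c) to match the cols layout
        return np.ascontiguousarray(
            self.w.data.transpose(0, 2, 3, 1).reshape(self.c_out, -1))

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ConfigurationError(
                f"{self.w.name}: expected {self.c_in} input channels, got {c}")
        k, p = self.k, self.k // 2
        # channels-last padded copy; patch extraction then moves contiguous blocks
        xcl = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
        xcl[:, p:p + h, p:p + w, :] = x.transpose(0, 2, 3, 1)
        if k == 1:
            cols = xcl.reshape(n * h * w, c)
        else:
            cols = np.empty((n, h, w, k * k * c), dtype=x.dtype)
            cv = cols.reshape(n, h, w, k, k, c)
            for i in range(k):
                for j in range(k):
                    cv[:, :, :, i, j, :] = xcl[:, i:i + h, j:j + w, :]
            cols = cols.reshape(n * h * w, k * k * c)
        wmat = self._wmat()
        out = cols @ wmat.T + self.b.data
        out = np.ascontiguousarray(out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2))
        return out, (x.shape, cols, wmat)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        (n, c, h, w), cols, wmat = cache
        k, p = self.k, self.k // 2
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.c_out)
        dwr = dyf.T @ cols
        self.w.grad += dwr.reshape(self.c_out, k, k, c).transpose(0, 3, 1, 2)
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ wmat
        if k == 1:
            dx = dcols.reshape(n, h, w, c)
        else:
            dv = dcols.reshape(n, h, w, k, k, c)
            dxcl = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dy.dtype)
            for i in range(k):
                for j in range(k):
                    dxcl[:, i:i + h, j:j + w, :] += dv[:, :, :, i, j, :]
            dx = dxcl[:, p:p + h, p:p + w, :]
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU(Module):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, dy):
        return dy * cache


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(c, dy)
        return dy


class ResidualBlock(Module):
    """conv -> ReLU -> conv with an identity skip connection.

    The skip-add is the block's third stage; the output stays linear so the
    block can sit in front of either a ReLU or a linear read-out.
    """

    def __init__(self, channels: int, k: int = 3, *, rng, name="res", dtype=np.float32):
        self.conv1 = Conv2d(channels, channels, k, rng=rng, name=name + ".conv1", dtype=dtype)
        self.relu = ReLU()
        self.conv2 = Conv2d(channels, channels, k, rng=rng, name=name + ".conv2", dtype=dtype)

    def forward(self, x):
        h1, c1 = self.conv1.forward(x)
        h2, c2 = self.relu.forward(h1)
        h3, c3 = self.conv2.forward(h2)
        return x + h3, (c1, c2, c3)

    def backward(self, cache, dy):
        c1, c2, c3 = cache
        d = self.conv2.backward(c3, dy)
        d = self.relu.backward(c2, d)
        d = self.conv1.backward(c1, d)
        return d + dy


class SelfAttention2d(Module):
    """Scaled dot-product spatial self-attention with identity skip.

    Query/key/value and the output projection are 1x1 convolutions.  On
    frames larger than ``window`` the map is split into non-overlapping
    ``window x window`` tiles and attention runs within each tile, bounding
    the cost at O(window^2) per pixel.  ``window=None`` attends over the
    whole frame.
    """

    def __init__(self, channels: int, *, rng, window: int | None = None,
                 name="attn", dtype=np.float32):
        self.channels = channels
        self.window = window
        self.q = Conv2d(channels, channels, 1, rng=rng, name=name + ".q", dtype=dtype)
        self.k = Conv2d(channels, channels, 1, rng=rng, name=name + ".k", dtype=dtype)
        self.v = Conv2d(channels, channels, 1, rng=rng, name=name + ".v", dtype=dtype)
        self.proj = Conv2d(channels, channels, 1, rng=rng, name=name + ".proj", dtype=dtype)

    def _tile(self, x, w_h, w_w):
        n, c, h, w = x.shape
        t = x.reshape(n, c, h // w_h, w_h, w // w_w, w_w)
        t = t.transpose(0, 2, 4, 1, 3, 5)  # (n, th, tw, c, w_h, w_w)
        return t.reshape(-1, c, w_h * w_w)

    def _untile(self, t, shape, w_h, w_w):
        n, c, h, w = shape
        t = t.reshape(n, h // w_h, w // w_w, c, w_h, w_w)
        t = t.transpose(0, 3, 1, 4, 2, 5)
        return np.ascontiguousarray(t.reshape(n, c, h, w))

    def _window_dims(self, h, w):
        if self.window is None:
            return h, w
        w_h = self.window if h % self.window == 0 else h
        w_w = self.window if w % self.window == 0 else w
        return w_h, w_w

    def forward(self, x):
        n, c, h, w = x.shape
        w_h, w_w = self._window_dims(h, w)
        q, cq = self.q.forward(x)
        k, ck = self.k.forward(x)
        v, cv = self.v.forward(x)
        qt, kt, vt = (self._tile(a, w_h, w_w) for a in (q, k, v))
        scale = 1.0 / math.sqrt(c)
        logits = np.einsum("mci,mcj->mij", qt, kt) * scale
        logits -= logits.max(axis=2, keepdims=True)
        att = np.exp(logits)
        att /= att.sum(axis=2, keepdims=True)
        ot = np.einsum("mij,mcj->mci", att, vt)
        o = self._untile(ot, x.shape, w_h, w_w)
        y, cp = self.proj.forward(o)
        return x + y, (x.shape, (w_h, w_w), cq, ck, cv, cp, qt, kt, vt, att)

    def backward(self, cache, dy):
        shape, (w_h, w_w), cq, ck, cv, cp, qt, kt, vt, att = cache
        n, c, h, w = shape
        do = self.proj.backward(cp, dy)
        dot = self._tile(do, w_h, w_w)
        datt = np.einsum("mci,mcj->mij", dot, vt)
        dvt = np.einsum("mij,mci->mcj", att, dot)
        dl = att * (datt - (datt * att).sum(axis=2, keepdims=True))
        scale = 1.0 / math.sqrt(c)
        dqt = np.einsum("mij,mcj->mci", dl, kt) * scale
        dkt = np.einsum("mij,mci->mcj", dl, qt) * scale
        dx = self.q.backward(cq, self._untile(dqt, shape, w_h, w_w))
        dx += self.k.backward(ck, self._untile(dkt, shape, w_h, w_w))
        dx += self.v.backward(cv, self._untile(dvt, shape, w_h, w_w))
        return dx + dy


class Adam:
    """Adaptive-moment optimizer over a parameter list."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
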