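"""A minimal, fully deterministic NumPy layer framework.

Implements exactly the pieces an attention U-Net needs — same-padded 2-D
convolution (im2col/BLAS), batch normalization, ReLU/sigmoid, inverted
dropout, 2x2 max pooling, nearest-neighbour upsampling, additive attention
gates — each with an analytically derived backward pass, plus an Adam
optimizer. Everything is float32 and driven by explicit
numpy.random.Generator instances, so a fixed seed reproduces training
bit-for-bit on a single CPU.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 convolution with 'same' zero padding (kernel 1 or odd)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        n, c, h, w = x.shape
        k = self.k
        if k == 1:
            y = np.einsum("nchw,oc->nohw", x, self.weight.value[:, :, 0, 0], optimize=True)
            y += self.bias.value[None, :, None, None]
            self._cache = (x.shape, x)
            return y.astype(DTYPE, copy=False)
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        wmat = self.weight.value.reshape(self.c_out, c * k * k)
        y = cols @ wmat.T + self.bias.value
        self._cache = (x.shape, cols)
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2).astype(DTYPE, copy=False)

    def backward(self, dy):
        (n, c, h, w), cached = self._cache
        k = self.k
        if k == 1:
            x = cached
            self.weight.grad += np.einsum("nohw,nchw->oc", dy, x, optimize=True)[:, :, None, None]
            self.bias.grad += dy.sum(axis=(0, 2, 3))
            dx = np.einsum("nohw,oc->nchw", dy, self.weight.value[:, :, 0, 0], optimize=True)
            return dx.astype(DTYPE, copy=False)
        cols = cached
        dout = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.weight.grad += (dout.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dout.sum(axis=0)
        wmat = self.weight.value.reshape(self.c_out, c * k * k)
        dcols = (dout @ wmat).reshape(n, h, w, c, k, k)
        p = k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(DTYPE)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(DTYPE, copy=False)

    def backward(self, dy):
        xhat, std, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return (dy * g / std[None, :, None, None]).astype(DTYPE, copy=False)
        dxhat = dy * g
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m)
        return (term / std[None, :, None, None]).astype(DTYPE, copy=False)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(DTYPE, copy=False)


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = (1.0 / (1.0 + np.exp(-x))).astype(DTYPE)
        return self._y

    def backward(self, dy):
        return (dy * self._y * (1 - self._y)).astype(DTYPE, copy=False)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(DTYPE) / keep
        return (x * self._mask).astype(DTYPE, copy=False)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(DTYPE, copy=False)


class MaxPool2(Layer):
    def forward(self, x, train):
        n, c, h, w = x.shape
        hh, ww = h // 2, w // 2
        xr = x.reshape(n, c, hh, 2, ww, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hh, ww, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        hh, ww = h // 2, w // 2
        dxr = np.zeros((n, c, hh, ww, 4), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None].astype(DTYPE), axis=-1)
        return dxr.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(DTYPE, copy=False)


class ConvBlock(Layer):
    """(Conv -> [BN] -> ReLU) x2 -> Dropout."""

    def __init__(self, c_in, c_out, rng, dropout_rng, dropout=0.1, batch_norm=True):
        self.layers: List[Layer] = []
        for cin in (c_in, c_out):
            self.layers.append(Conv2d(cin, c_out, 3, rng))
            if batch_norm:
                self.layers.append(BatchNorm2d(c_out))
            self.layers.append(ReLU())
        if dropout > 0:
            self.layers.append(Dropout(dropout, dropout_rng))

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class AttentionGate(Layer):
    """Additive attention gate on a skip connection.

    alpha = sigmoid(psi(relu(W_g g + W_x x))); returns x * alpha, where g
    is the (upsampled) decoder gating signal at the skip's resolution. The
    most recent per-pixel attention map (values in [0, 1]) is kept on
    ``last_attention`` for inspection.
    """

    def __init__(self, c_gate: int, c_skip: int, c_int: int, rng: np.random.Generator):
        self.wg = Conv2d(c_gate, c_int, 1, rng)
        self.wx = Conv2d(c_skip, c_int, 1, rng)
        self.psi = Conv2d(c_int, 1, 1, rng)
        self.relu = ReLU()
        self.sigmoid = Sigmoid()
        self.last_attention: Optional[np.ndarray] = None
        self._cache = None

    def params(self):
        return self.wg.params() + self.wx.params() + self.psi.params()

    def forward_gate(self, x, g, train):
        s = self.wg.forward(g, train) + self.wx.forward(x, train)
        a = self.relu.forward(s, train)
        alpha = self.sigmoid.forward(self.psi.forward(a, train), train)  # (N,1,H,W)
        self.last_attention = alpha
        self._cache = (x, alpha)
        return (x * alpha).astype(DTYPE, copy=False)

    def backward_gate(self, dy):
        x, alpha = self._cache
        dx_direct = dy * alpha
        dalpha = (dy * x).sum(axis=1, keepdims=True)
        da = self.relu.backward(self.psi.backward(self.sigmoid.backward(dalpha)))
        dg = self.wg.backward(da)
        dx = dx_direct + self.wx.backward(da)
        return dx.astype(DTYPE, copy=False), dg


class Adam:
    def __init__(self, params: List[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class AttentionUNet:
    """Encoder-decoder with attention-gated skip connections.

    depth poolings, base_filters channels at the top level doubling per
    level; 'same' padding keeps spatial dims, so any input whose sides are
    divisible by 2**depth maps to an output of identical spatial size with
    n_classes channels (logits).
    """

    def __init__(self, n_channels: int, n_classes: int, depth: int = 3,
                 base_filters: int = 16, dropout: float = 0.1,
                 batch_norm: bool = True, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.depth = depth
        self.n_channels, self.n_classes = n_channels, n_classes
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])

        f = [base_filters * 2 ** l for l in range(depth + 1)]
        self.encoders = []
        cin = n_channels
        for l in range(depth):
            self.encoders.append(ConvBlock(cin, f[l], rng, self.dropout_rng, dropout, batch_norm))
            cin = f[l]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = ConvBlock(f[depth - 1], f[depth], rng, self.dropout_rng,
                                    dropout, batch_norm)
        self.ups = []
        self.gates = []
        self.decoders = []
        for l in reversed(range(depth)):
            self.ups.append(Upsample2())
            self.gates.append(AttentionGate(f[l + 1], f[l], f[l], rng))
            self.decoders.append(ConvBlock(f[l + 1] + f[l], f[l], rng, self.dropout_rng,
                                           dropout, batch_norm))
        self.head = Conv2d(f[0], n_classes, 1, rng)

    def params(self) -> List[Param]:
        out = []
        for enc in self.encoders:
            out += enc.params()
        out += self.bottleneck.params()
        for g, d in zip(self.gates, self.decoders):
            out += g.params() + d.params()
        out += self.head.params()
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C, H, W) float input -> (N, K, H, W) logits."""
        if x.shape[1] != self.n_channels:
            raise ValueError(f"expected {self.n_channels} channels, got {x.shape[1]}")
        if x.shape[2] % 2 ** self.depth or x.shape[3] % 2 ** self.depth:
            raise ValueError(f"spatial dims must be divisible by {2 ** self.depth}")
        x = x.astype(DTYPE, copy=False)
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, gate, dec, skip in zip(self.ups, self.gates, self.decoders, reversed(skips)):
            g = up.forward(x, train)
            att = gate.forward_gate(skip, g, train)
            self._skip_channels.append((att.shape[1], g.shape[1]))
            x = dec.forward(np.concatenate([att, g], axis=1), train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits.astype(DTYPE, copy=False))
        # decoder stage i was built for encoder level depth-1-i; walking the
        # stages in reverse application order therefore yields skip grads for
        # encoder levels 0, 1, ..., depth-1 in that sequence
        dskips = []
        for i in reversed(range(self.depth)):
            dcat = self.decoders[i].backward(dy)
            c_att, _ = self._skip_channels[i]
            datt, dg1 = dcat[:, :c_att], dcat[:, c_att:]
            dskip, dg2 = self.gates[i].backward_gate(datt)
            dy = self.ups[i].backward(dg1 + dg2)
            dskips.append(dskip)
        dy = self.bottleneck.backward(dy)
        for l in reversed(range(self.depth)):
            dy = self.pools[l].backward(dy)
            dy = dy + dskips[l]
            dy = self.encoders[l].backward(dy)

    def state_arrays(self) -> List[np.ndarray]:
        """All learnable and running-stat arrays, for checkpointing."""
        arrs = [p.value for p in self.params()]
        for layer in self._bn_layers():
            arrs += [layer.running_mean, layer.running_var]
        return arrs

    def load_state_arrays(self, arrs: List[np.ndarray]) -> None:
        params = self.params()
        for p, a in zip(params, arrs[:len(params)]):
            p.value[...] = a
        rest = arrs[len(params):]
        for layer, (rm, rv) in zip(self._bn_layers(), zip(rest[0::2], rest[1::2])):
            layer.running_mean = rm.astype(DTYPE)
            layer.running_var = rv.astype(DTYPE)

    def _bn_layers(self):
        blocks = self.encoders + [self.bottleneck] + self.decoders
        for b in blocks:
            for l in b.layers:
                if isinstance(l, BatchNorm2d):
                    yield l


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
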