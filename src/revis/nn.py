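"""Minimal reverse-mode autodiff over NumPy arrays, NCHW layout.

Supplies exactly the pieces the convolutional model zoo needs: im2col
convolution, fractionally-strided (transposed) convolution, group and batch
normalisation, ReLU, max/adaptive-average pooling, channel concatenation,
linear layers, cross-entropy, and Adam.  Gradients flow through a taped graph
of :class:`Tensor` nodes; ``no_grad()`` disables taping for pure inference.

Everything is float64 by default; these models run at desk scale, where
numerical transparency beats throughput.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A node in the autodiff tape wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False, parents=(), bw=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._bw = bw

    @property
    def shape(self):
        return self.data.shape

    # -- graph ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._bw is None:
                continue
            for parent, pg in zip(t._parents, t._bw(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*ts: Tensor) -> bool:
    return _GRAD_ENABLED and any(
        t.requires_grad or t._parents for t in ts)


def _make(data, parents, bw) -> Tensor:
    if _track(*parents):
        return Tensor(data, parents=tuple(parents), bw=bw)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Elementwise / reduction primitives
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data + b.data
    return _make(out, (a, b), lambda g: (_unbroadcast(g, a.shape),
                                         _unbroadcast(g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data * b.data
    return _make(out, (a, b), lambda g: (_unbroadcast(g * b.data, a.shape),
                                         _unbroadcast(g * a.data, b.shape)))


def power(a, p: float) -> Tensor:
    a = astensor(a)
    out = a.data ** p
    return _make(out, (a,), lambda g: (g * p * a.data ** (p - 1),))


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in np.atleast_1d(axis)])

    def bw(g):
        gg = np.asarray(g)
        if not keepdims and axis is not None:
            gg = np.expand_dims(gg, axis)
        return (np.broadcast_to(gg, a.shape) / n,)

    return _make(out, (a,), bw)


def relu(a) -> Tensor:
    a = astensor(a)
    pos = a.data > 0
    return _make(a.data * pos, (a,), lambda g: (g * pos,))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return _make(a.data.reshape(shape), (a,),
                 lambda g: (g.reshape(a.shape),))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out, tuple(tensors), bw)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data @ b.data
    return _make(out, (a, b), lambda g: (g @ b.data.T, a.data.T @ g))


# ---------------------------------------------------------------------------
# Convolution primitives
# ---------------------------------------------------------------------------


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    xp = _pad2d(x, pad)
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    return np.einsum("nchwkl,ockl->nohw", win, w, optimize=True)


def _conv_bwd(x: np.ndarray, w: np.ndarray, gy: np.ndarray,
              stride: int, pad: int) -> tuple[np.ndarray, np.ndarray]:
    xp = _pad2d(x, pad)
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    gw = np.einsum("nchwkl,nohw->ockl", win, gy, optimize=True)
    # input gradient: full correlation of the stride-dilated gy with flipped w
    n, o, ho, wo = gy.shape
    hd, wd = (ho - 1) * stride + 1, (wo - 1) * stride + 1
    gz = np.zeros((n, o, hd, wd), dtype=gy.dtype)
    gz[:, :, ::stride, ::stride] = gy
    gz = _pad2d(gz, 0)
    gzp = np.pad(gz, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    wf = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, kh, kw)
    gxp = _conv_fwd(gzp, wf, 1, 0)
    # gxp covers the padded input up to kernel-reach; crop/pad to x's size
    gx = np.zeros_like(xp)
    h = min(gxp.shape[2], xp.shape[2])
    wdt = min(gxp.shape[3], xp.shape[3])
    gx[:, :, :h, :wdt] = gxp[:, :, :h, :wdt]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx, gw


def conv2d(x, w, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weights, no bias."""
    x, w = astensor(x), astensor(w)
    out = _conv_fwd(x.data, w.data, stride, pad)

    def bw(g):
        gx, gw = _conv_bwd(x.data, w.data, g, stride, pad)
        return gx, gw

    return _make(out, (x, w), bw)


def conv_transpose2d(x, w, stride: int = 2, pad: int = 1) -> Tensor:
    """Fractionally-strided convolution, weights shaped (Cin, Cout, kh, kw).

    Output spatial size is ``(H - 1) * stride - 2 * pad + k``; with the
    default kernel 4 / stride 2 / pad 1 it exactly doubles the input.
    """
    x, w = astensor(x), astensor(w)
    kh, kw = w.shape[2], w.shape[3]

    def dilate_pad(xd):
        n, c, h, wid = xd.shape
        hd, wd = (h - 1) * stride + 1, (wid - 1) * stride + 1
        z = np.zeros((n, c, hd, wd), dtype=xd.dtype)
        z[:, :, ::stride, ::stride] = xd
        return np.pad(z, ((0, 0), (0, 0), (kh - 1 - pad, kh - 1 - pad),
                          (kw - 1 - pad, kw - 1 - pad)))

    wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cout, Cin, kh, kw)
    xd = dilate_pad(x.data)
    out = _conv_fwd(xd, wf, 1, 0)

    def bw(g):
        g_xd, g_wf = _conv_bwd(xd, wf, g, 1, 0)
        lo = kh - 1 - pad
        if lo:
            g_xd = g_xd[:, :, lo:-lo or None, lo:-lo or None]
        gx = g_xd[:, :, ::stride, ::stride]
        gw = g_wf.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        return gx, gw

    return _make(out, (x, w), bw)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def max_pool2d(x, kernel: int, stride: int, pad: int = 0) -> Tensor:
    x = astensor(x)
    xp = _pad2d(x.data, pad)
    if pad:
        xp = xp.copy()
        xp[:, :, :pad, :] = -np.inf
        xp[:, :, -pad:, :] = -np.inf
        xp[:, :, :, :pad] = -np.inf
        xp[:, :, :, -pad:] = -np.inf
    win = sliding_window_view(xp, (kernel, kernel),
                              axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    am = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]

    def bw(g):
        gxp = np.zeros(xp.shape, dtype=float)
        oh, ow = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = oh[None, None] * stride + am // kernel
        cols = ow[None, None] * stride + am % kernel
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(gxp, (np.broadcast_to(ni, am.shape),
                        np.broadcast_to(ci, am.shape), rows, cols), g)
        if pad:
            gxp = gxp[:, :, pad:-pad, pad:-pad]
        return (gxp,)

    return _make(out, (x,), bw)


def adaptive_avg_pool2d(x, out_hw: int) -> Tensor:
    """Average pooling to a square ``out_hw`` target, PyTorch bin convention
    (start floor(i*H/o), end ceil((i+1)*H/o))."""
    x = astensor(x)
    n, c, h, w = x.shape
    if out_hw == h == w:
        return _make(x.data.copy(), (x,), lambda g: (g,))
    if out_hw == 1:
        out = x.data.mean(axis=(2, 3), keepdims=True)
        return _make(out, (x,),
                     lambda g: (np.broadcast_to(g, x.shape) / (h * w),))
    rb = [(int(np.floor(i * h / out_hw)), int(np.ceil((i + 1) * h / out_hw)))
          for i in range(out_hw)]
    cb = [(int(np.floor(j * w / out_hw)), int(np.ceil((j + 1) * w / out_hw)))
          for j in range(out_hw)]
    out = np.empty((n, c, out_hw, out_hw), dtype=float)
    for i, (r0, r1) in enumerate(rb):
        for j, (c0, c1) in enumerate(cb):
            out[:, :, i, j] = x.data[:, :, r0:r1, c0:c1].mean(axis=(2, 3))

    def bw(g):
        gx = np.zeros(x.shape, dtype=float)
        for i, (r0, r1) in enumerate(rb):
            for j, (c0, c1) in enumerate(cb):
                gx[:, :, r0:r1, c0:c1] += (
                    g[:, :, i:i + 1, j:j + 1] / ((r1 - r0) * (c1 - c0)))
        return (gx,)

    return _make(out, (x,), bw)


def channel_mean(x) -> Tensor:
    """Mean over the channel axis, keeping a single channel."""
    return mean(x, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of logits (N, C)."""
    logits = astensor(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    ll = -np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean()

    def bw(g):
        gp = p.copy()
        gp[np.arange(n), labels] -= 1.0
        return (g * gp / n,)

    return _make(np.asarray(ll), (logits,), bw)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Tiny module system: registered parameters + child modules by name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __getattr__(self, name):
        for store in ("_children", "_params"):
            d = self.__dict__.get(store)
            if d is not None and name in d:
                return d[name]
        raise AttributeError(name)

    def register(self, name: str, tensor: Tensor) -> Tensor:
        tensor.requires_grad = True
        self._params[name] = tensor
        return tensor

    def add_module(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        for k, v in state.items():
            own[k].data = np.asarray(v, dtype=float).copy()


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel * kernel
        self.w = self.register(
            "w", Tensor(_he_init(rng, (c_out, c_in, kernel, kernel), fan_in)))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = pad
        fan_in = c_in * kernel * kernel
        self.w = self.register(
            "w", Tensor(_he_init(rng, (c_in, c_out, kernel, kernel), fan_in)))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w = self.register("w", Tensor(_he_init(rng, (n_in, n_out), n_in)))
        self.b = self.register("b", Tensor(np.zeros(n_out)))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.w), self.b)


class GroupNorm(Module):
    """Group normalisation with per-channel affine parameters."""

    def __init__(self, channels: int, groups: int = 32, eps: float = 1e-5):
        super().__init__()
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = self.register("gamma", Tensor(np.ones((1, channels, 1, 1))))
        self.beta = self.register("beta", Tensor(np.zeros((1, channels, 1, 1))))

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = reshape(x, (n, g, c // g * h * w))
        mu = mean(xg, axis=2, keepdims=True)
        xc = xg - mu
        var = mean(mul(xc, xc), axis=2, keepdims=True)
        inv = power(add(var, self.eps), -0.5)
        xn = reshape(mul(xc, inv), (n, c, h, w))
        return add(mul(xn, self.gamma), self.beta)


class BatchNorm2d(Module):
    """Batch normalisation (NCHW); batch statistics while training, running
    statistics at evaluation."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.register("gamma", Tensor(np.ones((1, channels, 1, 1))))
        self.beta = self.register("beta", Tensor(np.zeros((1, channels, 1, 1))))
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = mean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = mean(mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            inv = power(add(var, self.eps), -0.5)
            xn = mul(xc, inv)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xn = mul(x - Tensor(self.running_mean), Tensor(inv))
        return add(mul(xn, self.gamma), self.beta)


class Adam:
    """Adam over an explicit (name, Tensor) parameter list."""

    def __init__(self, params: Iterable[tuple[str, Tensor]], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in self.params}
        self.v = {n: np.zeros_like(p.data) for n, p in self.params}

    def step(self):
        self.t += 1
        for n, p in self.params:
            if p.grad is None:
                continue
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * p.grad
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * p.grad ** 2
            mh = self.m[n] / (1 - self.b1 ** self.t)
            vh = self.v[n] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for _, p in self.params:
            p.grad = None
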