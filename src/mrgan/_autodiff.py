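"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical engine behind the synthesis and discriminator
networks: a small tape-based autodiff with exactly the operations the
translation networks need (2-D convolution via im2col, fractionally
strided convolution via zero-stuffing, instance normalization, the usual
pointwise nonlinearities) plus an Adam optimizer.  Data layout is NCHW
throughout.  Every layer gradient is validated against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "conv2d",
    "reflect_pad2d",
    "zero_upsample2d",
    "nearest_upsample2d",
    "instance_norm2d",
    "concat_channels",
    "relu",
    "leaky_relu",
    "tanh",
    "sigmoid",
    "clamp",
    "log",
    "absolute",
    "square",
    "mean",
    "Conv2d",
    "Adam",
]


class Tensor:
    """An ndarray plus the tape entry that produced it.

    ``_parents`` holds ``(parent, vjp)`` pairs where ``vjp`` maps the
    gradient w.r.t. this tensor to the gradient contribution for the
    parent.  Tensors created from plain data have an empty tape.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = tuple(_parents)

    # -- graph -----------------------------------------------------------
    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, vjp in node._parents:
                if not (parent.requires_grad or parent._parents):
                    continue
                g = vjp(node.grad)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- convenience -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return _add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return _mul(self, -1.0)

    def __sub__(self, other):
        return _add(self, _neg_other(other))

    def __rsub__(self, other):
        return _add(_mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division not supported")
        return _mul(self, 1.0 / float(other))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _neg_other(other):
    return _mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other, dtype=np.float64)


def _track(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def _add(a, b):
    a = as_tensor(a)
    b = as_tensor(b)
    out_data = a.data + b.data
    if not _track(a, b):
        return Tensor(out_data)
    parents = [
        (a, lambda g, sh=a.data.shape: _unbroadcast(g, sh)),
        (b, lambda g, sh=b.data.shape: _unbroadcast(g, sh)),
    ]
    return Tensor(out_data, _parents=parents)


def _mul(a, b):
    a = as_tensor(a)
    b = as_tensor(b)
    out_data = a.data * b.data
    if not _track(a, b):
        return Tensor(out_data)
    parents = [
        (a, lambda g, bd=b.data, sh=a.data.shape: _unbroadcast(g * bd, sh)),
        (b, lambda g, ad=a.data, sh=b.data.shape: _unbroadcast(g * ad, sh)),
    ]
    return Tensor(out_data, _parents=parents)


def _pointwise(x, fwd: Callable, dfun: Callable) -> Tensor:
    x = as_tensor(x)
    out_data = fwd(x.data)
    if not _track(x):
        return Tensor(out_data)
    return Tensor(out_data, _parents=[(x, lambda g: g * dfun(x.data, out_data))])


def relu(x):
    return _pointwise(x, lambda d: np.maximum(d, 0.0), lambda d, o: (d > 0).astype(np.float64))


def leaky_relu(x, slope: float = 0.2):
    return _pointwise(
        x,
        lambda d: np.where(d >= 0, d, slope * d),
        lambda d, o: np.where(d >= 0, 1.0, slope),
    )


def tanh(x):
    return _pointwise(x, np.tanh, lambda d, o: 1.0 - o * o)


def sigmoid(x):
    def fwd(d):
        out = np.empty_like(d)
        pos = d >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    return _pointwise(x, fwd, lambda d, o: o * (1.0 - o))


def log(x):
    return _pointwise(x, np.log, lambda d, o: 1.0 / d)


def absolute(x):
    return _pointwise(x, np.abs, lambda d, o: np.sign(d))


def square(x):
    return _pointwise(x, np.square, lambda d, o: 2.0 * d)


def clamp(x, lo: float, hi: float):
    """Clip values to [lo, hi]; gradient passes through inside the range."""
    return _pointwise(
        x,
        lambda d: np.clip(d, lo, hi),
        lambda d, o: ((d >= lo) & (d <= hi)).astype(np.float64),
    )


def mean(x):
    x = as_tensor(x)
    out_data = np.asarray(x.data.mean())
    if not _track(x):
        return Tensor(out_data)
    n = x.data.size
    sh = x.data.shape
    return Tensor(out_data, _parents=[(x, lambda g: np.full(sh, float(g) / n))])


def concat_channels(a, b):
    """Concatenate two NCHW tensors along the channel axis."""
    a = as_tensor(a)
    b = as_tensor(b)
    out_data = np.concatenate([a.data, b.data], axis=1)
    if not _track(a, b):
        return Tensor(out_data)
    ca = a.data.shape[1]
    parents = [
        (a, lambda g: g[:, :ca]),
        (b, lambda g: g[:, ca:]),
    ]
    return Tensor(out_data, _parents=parents)


# ---------------------------------------------------------------------------
# spatial ops
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=np.float64)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * ho:stride,
                                 j:j + stride * wo:stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, xshape: tuple, kh: int, kw: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    dx = np.zeros(xshape, dtype=np.float64)
    d6 = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += d6[:, :, i, j]
    return dx


def conv2d(x, w, b=None, stride: int = 1, pad=0):
    """2-D cross-correlation with zero padding; weight layout (F, C, kh, kw).

    ``pad`` is either a symmetric int or a ``(before, after)`` tuple
    applied to both spatial axes (asymmetric padding makes even-kernel
    stride-1 convolutions size-preserving).
    """
    x = as_tensor(x)
    w = as_tensor(w)
    n, c, h, wdt = x.data.shape
    f, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {cw}")
    pl, pr = (pad, pad) if isinstance(pad, int) else pad
    xd = x.data
    if pl or pr:
        xd = np.pad(xd, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
    if xd.shape[2] < kh or xd.shape[3] < kw:
        raise ValueError(
            f"conv2d input {xd.shape[2]}x{xd.shape[3]} smaller than kernel {kh}x{kw}"
        )
    cols, ho, wo = _im2col(xd, kh, kw, stride)
    w2 = w.data.reshape(f, -1)
    out_data = np.matmul(w2, cols).reshape(n, f, ho, wo)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, f, 1, 1)
    tracked = _track(x, w) or (b is not None and _track(b))
    if not tracked:
        return Tensor(out_data)

    pshape = xd.shape

    def grad_x(g):
        g2 = g.reshape(n, f, ho * wo)
        dcols = np.matmul(w2.T, g2)
        dxp = _col2im(dcols, pshape, kh, kw, stride, ho, wo)
        if pl or pr:
            return dxp[:, :, pl:pl + h, pl:pl + wdt]
        return dxp

    def grad_w(g):
        g2 = g.reshape(n, f, ho * wo)
        dw2 = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
        return dw2.reshape(f, c, kh, kw)

    parents = [(x, grad_x), (w, grad_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out_data, _parents=parents)


def reflect_pad2d(x, pad: int):
    x = as_tensor(x)
    out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="reflect")
    if not _track(x):
        return Tensor(out_data)
    n, c, h, w = x.data.shape
    idx = np.pad(np.arange(h * w).reshape(h, w), pad, mode="reflect").ravel()

    def grad_x(g):
        dx = np.zeros((n, c, h * w), dtype=np.float64)
        np.add.at(dx, (slice(None), slice(None), idx), g.reshape(n, c, -1))
        return dx.reshape(n, c, h, w)

    return Tensor(out_data, _parents=[(x, grad_x)])


def zero_upsample2d(x, factor: int = 2):
    """Insert ``factor - 1`` zeros between pixels (fractional striding)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = np.zeros((n, c, h * factor, w * factor), dtype=np.float64)
    out_data[:, :, ::factor, ::factor] = x.data
    if not _track(x):
        return Tensor(out_data)
    return Tensor(out_data, _parents=[(x, lambda g: g[:, :, ::factor, ::factor].copy())])


def nearest_upsample2d(x, factor: int = 2):
    """Nearest-neighbour upsampling (each pixel becomes a factor² block)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    if not _track(x):
        return Tensor(out_data)

    def grad_x(g):
        return g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))

    return Tensor(out_data, _parents=[(x, grad_x)])


def instance_norm2d(x, eps: float = 1e-5):
    """Per-sample, per-channel feature normalization (no affine parameters)."""
    x = as_tensor(x)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    if not _track(x):
        return Tensor(xhat)

    def grad_x(g):
        gm = g.mean(axis=(2, 3), keepdims=True)
        gxm = (g * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (g - gm - xhat * gxm)

    return Tensor(xhat, _parents=[(x, grad_x)])


# ---------------------------------------------------------------------------
# parameters and optimization
# ---------------------------------------------------------------------------

class Conv2d:
    """Convolution layer with Gaussian(0, init_sd) weights and zero bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator, init_sd: float = 0.02):
        self.weight = Tensor(
            rng.normal(0.0, init_sd, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def __call__(self, x) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Adam:
    """Adam with per-call learning rate (the schedule supplies it)."""

    def __init__(self, params: Iterable[Tensor], beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [a.copy() for a in self.m],
            "v": [a.copy() for a in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a, dtype=np.float64).copy() for a in state["m"]]
        self.v = [np.asarray(a, dtype=np.float64).copy() for a in state["v"]]
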