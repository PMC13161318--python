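"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training objective of this package — the soft-assignment multivariate
logrank statistic with a balance barrier — must be differentiated end to end
through a neural network.  This module provides the small set of array
operations that the objective and the bundled MLP/CNN architectures require:
broadcasting arithmetic, matrix products, reductions, elementwise transforms,
a matrix inverse (for the quadratic form of the statistic), softmax, and 2D
convolution / max-pooling.

Gradients follow the standard vector-Jacobian-product rules; correctness of
every primitive is pinned by central finite-difference tests.  The engine is
deliberately eager and single-threaded: graphs here are shallow (a few dozen
nodes per mini-batch) and determinism matters more than throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "matmul",
    "inv",
    "softmax",
    "relu",
    "clip",
    "conv2d",
    "maxpool2d",
]


class Tensor:
    """A numpy array plus gradient bookkeeping.

    Operators (+, -, *, /, **, @) build a computation graph when any operand
    has ``requires_grad=True``; :meth:`backward` then accumulates gradients
    into every requiring leaf.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    # make numpy defer to Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None  # callable: upstream grad -> tuple of parent grads

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Accumulate d(self)/d(leaf) into every graph leaf's ``.grad``."""
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        return _binary(self, other, np.add, lambda a, b, g: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda a, b, g: (g, -g))

    def __rsub__(self, other):
        return astensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda a, b, g: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(
            self, other, np.divide, lambda a, b, g: (g / b, -g * a / (b * b))
        )

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __neg__(self):
        return _unary(self, -self.data, lambda g: -g)

    def __pow__(self, exponent):
        e = float(exponent)
        x = self.data
        return _unary(self, x**e, lambda g: g * e * x ** (e - 1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(astensor(other), self)

    def __getitem__(self, idx):
        data = self.data[idx]

        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return _node(data, (self,), vjp)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return _node(data, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- shape & misc
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return _node(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    @property
    def T(self):
        return _node(self.data.T, (self,), lambda g: (g.T,))

    def exp(self):
        out = np.exp(self.data)
        return _unary(self, out, lambda g: g * out)

    def log(self):
        x = self.data
        return _unary(self, np.log(x), lambda g: g / x)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unary(x: Tensor, data, dvjp) -> Tensor:
    return _node(data, (x,), lambda g: (dvjp(g),))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, vjp) -> Tensor:
    a, b = astensor(a), astensor(b)
    ad, bd = a.data, b.data

    def wrapped(g):
        ga, gb = vjp(ad, bd, g)
        return (_unbroadcast(ga, ad.shape), _unbroadcast(gb, bd.shape))

    return _node(fwd(ad, bd), (a, b), wrapped)


def matmul(a, b) -> Tensor:
    """Matrix product for 2D@2D, 2D@1D and 1D@2D operands."""
    a, b = astensor(a), astensor(b)
    ad, bd = a.data, b.data
    out = ad @ bd

    def vjp(g):
        if ad.ndim == 2 and bd.ndim == 2:
            return (g @ bd.T, ad.T @ g)
        if ad.ndim == 2 and bd.ndim == 1:
            return (np.outer(g, bd), ad.T @ g)
        if ad.ndim == 1 and bd.ndim == 2:
            return (bd @ g, np.outer(ad, g))
        if ad.ndim == 1 and bd.ndim == 1:
            return (g * bd, g * ad)
        raise ValueError("unsupported matmul operand ranks")

    return _node(out, (a, b), vjp)


def relu(x) -> Tensor:
    x = astensor(x)
    mask = x.data > 0
    return _unary(x, np.where(mask, x.data, 0.0), lambda g: g * mask)


def clip(x, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the un-clamped region."""
    x = astensor(x)
    mask = (x.data > lo) & (x.data < hi)
    return _unary(x, np.clip(x.data, lo, hi), lambda g: g * mask)


def inv(x) -> Tensor:
    """Inverse of a small square matrix (used on the reduced covariance)."""
    x = astensor(x)
    out = np.linalg.inv(x.data)
    return _unary(x, out, lambda g: -out.T @ g @ out.T)


def softmax(x, axis: int = -1) -> Tensor:
    x = astensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return _node(y, (x,), vjp)


def conv2d(x, w, b, padding: str = "same") -> Tensor:
    """2D convolution (cross-correlation) with zero padding and stride 1.

    ``x``: (N, C, H, W), ``w``: (F, C, kh, kw), ``b``: (F,).  Even kernel
    sizes pad one pixel more on the trailing edge, so output spatial size
    always equals input size.
    """
    if padding != "same":
        raise ValueError("only 'same' padding is supported")
    x, w, b = astensor(x), astensor(w), astensor(b)
    xd, wd, bd = x.data, w.data, b.data
    n, c, h, wid = xd.shape
    f, c2, kh, kw = wd.shape
    if c2 != c:
        raise ValueError(f"input has {c} channels but kernel expects {c2}")
    ph0, ph1 = (kh - 1) // 2, kh // 2
    pw0, pw1 = (kw - 1) // 2, kw // 2
    xp = np.pad(xd, ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1)))
    # (N, C, H, W, kh, kw) sliding view -> columns (N*H*W, C*kh*kw)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wid, c * kh * kw)
    w2 = wd.reshape(f, -1)
    out = (cols @ w2.T + bd).reshape(n, h, wid, f).transpose(0, 3, 1, 2)

    def vjp(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * h * wid, f)
        gb = g2.sum(axis=0) if b.requires_grad else None
        gw = (g2.T @ cols).reshape(wd.shape) if w.requires_grad else None
        gx = None
        if x.requires_grad:  # images are usually constants: skip the scatter
            gcols = (g2 @ w2).reshape(n, h, wid, c, kh, kw)
            gxp = np.zeros_like(xp)
            for p in range(kh):
                for q in range(kw):
                    gxp[:, :, p : p + h, q : q + wid] += gcols[
                        :, :, :, :, p, q
                    ].transpose(0, 3, 1, 2)
            gx = gxp[:, :, ph0 : ph0 + h, pw0 : pw0 + wid]
        return (gx, gw, gb)

    return _node(out, (x, w, b), vjp)


def maxpool2d(x, size: int) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible by size."""
    x = astensor(x)
    xd = x.data
    n, c, h, w = xd.shape
    if h % size or w % size:
        raise ValueError(f"spatial dims {h}x{w} not divisible by pool size {size}")
    ho, wo = h // size, w // size
    xr = xd.reshape(n, c, ho, size, wo, size).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, ho, wo, size * size)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, ho, wo, size, size).transpose(0, 1, 2, 4, 3, 5)
        return (gr.reshape(n, c, h, w),)

    return _node(out, (x,), vjp)
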