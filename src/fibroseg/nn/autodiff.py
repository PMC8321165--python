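"""Reverse-mode automatic differentiation on numpy arrays.

`Var` wraps an ndarray and records the operations applied to it; calling
:meth:`Var.backward` on a scalar result accumulates gradients into every
upstream `Var`. The op set is exactly what encoder–decoder segmentation
networks and the Tversky loss need: broadcasting arithmetic, exp/pow,
reductions, convolutions (plain, dilated, strided, transposed), 2×2 max
pooling, nearest 2× upsampling, channel concatenation/slicing and soft-max.
"""

from __future__ import annotations

import numpy as np

from . import _convops as C


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Var:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_grad_fn")

    def __init__(self, data, parents=(), grad_fn=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = parents
        self._grad_fn = grad_fn

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Var] = []
        seen: set[int] = set()
        stack: list[tuple[Var, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here can be ~10^3 nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._grad_fn is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._grad_fn(node.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + g

    # -- arithmetic --------------------------------------------------------
    def _coerce(self, other) -> "Var":
        return other if isinstance(other, Var) else Var(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        o = self._coerce(other)
        return Var(self.data + o.data, (self, o),
                   lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Var(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Var(self.data * o.data, (self, o),
                   lambda g: (_unbroadcast(g * o.data, self.shape),
                              _unbroadcast(g * self.data, o.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return Var(self.data / o.data, (self, o),
                   lambda g: (_unbroadcast(g / o.data, self.shape),
                              _unbroadcast(-g * self.data / (o.data ** 2), o.shape)))

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def pow_const(self, p: float):
        return Var(self.data ** p, (self,), lambda g: (g * p * self.data ** (p - 1),))

    def exp(self):
        out_data = np.exp(self.data)
        return Var(out_data, (self,), lambda g: (g * out_data,))

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Var(out_data, (self,), grad_fn)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def item(self) -> float:
        return float(self.data)


# ---------------------------------------------------------------------------
# elementwise non-linearities
# ---------------------------------------------------------------------------

def relu(x: Var) -> Var:
    mask = x.data > 0
    return Var(np.where(mask, x.data, 0), (x,), lambda g: (g * mask,))


def neg_part(x: Var) -> Var:
    """min(x, 0); building block of PReLU."""
    mask = x.data < 0
    return Var(np.where(mask, x.data, 0), (x,), lambda g: (g * mask,))


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(vars_: list[Var], axis: int = 1) -> Var:
    data = np.concatenate([v.data for v in vars_], axis=axis)
    sizes = [v.shape[axis] for v in vars_]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Var(data, tuple(vars_), grad_fn)


def narrow(x: Var, axis: int, start: int, length: int) -> Var:
    """Slice `length` entries from `start` along `axis`."""
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def grad_fn(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        return (full,)

    return Var(x.data[idx], (x,), grad_fn)


def pad_channels(x: Var, extra: int) -> Var:
    """Append `extra` all-zero channels (axis 1)."""
    n, c, h, w = x.shape
    data = np.concatenate([x.data, np.zeros((n, extra, h, w), dtype=x.data.dtype)], axis=1)
    return Var(data, (x,), lambda g: (g[:, :c],))


# ---------------------------------------------------------------------------
# convolution / pooling / upsampling
# ---------------------------------------------------------------------------

def conv2d(x: Var, w: Var, b: Var | None = None, stride=(1, 1), dilation=(1, 1),
           pad=((0, 0), (0, 0))) -> Var:
    parents = (x, w) if b is None else (x, w, b)
    out = C.conv2d_fwd(x.data, w.data, None if b is None else b.data, stride, dilation, pad)

    def grad_fn(g):
        gx = C.conv2d_bwd_x(g, w.data, x.shape, stride, dilation, pad)
        gw = C.conv2d_bwd_w(x.data, g, w.shape, stride, dilation, pad)
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Var(out, parents, grad_fn)


def conv2d_transpose(x: Var, w: Var, b: Var | None = None, stride=(2, 2),
                     pad=((0, 0), (0, 0)), out_hw: tuple[int, int] | None = None) -> Var:
    """Transposed convolution: the adjoint of `conv2d` with the same geometry.

    `w` has shape (in_channels, out_channels, kh, kw): viewed from the adjoint
    ordinary convolution (which maps the *output* of this op back to its
    *input*), that is the usual (Cout_conv, Cin_conv, kh, kw) orientation, so
    the low-level kernels are reused directly.
    """
    cout = w.shape[1]
    n = x.shape[0]
    if out_hw is None:
        out_hw = (x.shape[2] * stride[0], x.shape[3] * stride[1])
    big_shape = (n, cout, out_hw[0], out_hw[1])
    out = C.conv2d_bwd_x(x.data, w.data, big_shape, stride, (1, 1), pad)
    if b is not None:
        out = out + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def grad_fn(g):
        gx = C.conv2d_fwd(g, w.data, None, stride, (1, 1), pad)
        gw = C.conv2d_bwd_w(g, x.data, w.shape, stride, (1, 1), pad)
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Var(out, parents, grad_fn)


def maxpool2x2(x: Var) -> Var:
    n, c, h, w = x.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 needs even plane sizes"
    windows = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(n, c, h // 2, w // 2, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def grad_fn(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(n, c, h, w),)

    return Var(out, (x,), grad_fn)


def upsample2x(x: Var) -> Var:
    """Nearest-neighbour 2× upsampling (parameter-free)."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.shape

    def grad_fn(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Var(out, (x,), grad_fn)


def softmax(x: Var, axis: int = 1) -> Var:
    # subtracting the (detached) max is exact: softmax is shift-invariant
    shifted = x + Var(-x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
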