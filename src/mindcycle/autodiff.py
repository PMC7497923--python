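"""Minimal reverse-mode automatic differentiation over numpy arrays.

The registration objective (MIND content loss of a trilinearly warped
volume, displacement regularization, cycle reconstruction) must be
differentiated with respect to network parameters and displacement
fields.  This module provides a small tape-based engine with exactly the
operations the package needs: elementwise arithmetic, exp/tanh/relu/abs,
reductions (sum/mean/max), matmul, reshape/concatenate/pad, and gather
(`take`) whose adjoint is a scatter-add.  Gather is the workhorse: shifted
reads for MIND patch distances, im2col for 3D convolution, and corner
lookups for trilinear warping are all expressed through it.

Gradients are accumulated with float64 throughout; there is no GPU path
and no broadcasting beyond numpy semantics (adjoints un-broadcast by
summing over expanded axes).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack",
    "exp",
    "tanh",
    "relu",
    "absolute",
    "maximum_along",
    "clip",
    "take",
    "shift_axis",
    "pad_zero",
    "matmul",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_shared")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None
        self._grad_shared = False

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    @property
    def size(self):
        return self.value.size

    def _accumulate(self, g):
        # first contribution is held by reference (producers hand over
        # freshly built or read-only arrays); a second contribution forces
        # an owned copy before in-place accumulation
        if self.grad is None:
            self.grad = g if isinstance(g, np.ndarray) else np.asarray(g)
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def backward(self):
        """Reverse sweep seeding d(self)/d(self) = 1 (scalar outputs)."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        self._grad_shared = False
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None
        self._grad_shared = False

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return _unary(self, np.negative, lambda g, a: -g)

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents supported")
        return _unary(self, lambda a: np.power(a, exponent),
                      lambda g, a: g * exponent * np.power(a, exponent - 1))

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.value.shape
        out = Tensor(self.value.reshape(shape))
        if _track(self):
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.reshape(src_shape))
        return out

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.value.transpose(axes))
        if _track(self):
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def sum(self, axis=None, keepdims: bool = False):
        src_shape = self.value.shape
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims))

        def bwd(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, src_shape))

        if _track(self):
            out.requires_grad = True
            out._parents = (self,)
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.value.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.value.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def item(self) -> float:
        return float(self.value)


def _track(*tensors) -> bool:
    return any(isinstance(t, Tensor) and t.requires_grad for t in tensors)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (adjoint of numpy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _binary(a, b, fwd, grads):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.value, b.value))
    if _track(a, b):
        out.requires_grad = True
        out._parents = tuple(t for t in (a, b) if t.requires_grad)

        def bwd(g):
            ga, gb = grads(g, a.value, b.value)
            if a.requires_grad:
                a._accumulate(_unbroadcast(ga, a.value.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(gb, b.value.shape))

        out._backward = bwd
    return out


def _unary(a, fwd, grad):
    a = as_tensor(a)
    out = Tensor(fwd(a.value))
    if _track(a):
        out.requires_grad = True
        out._parents = (a,)
        out._backward = lambda g: a._accumulate(grad(g, a.value))
    return out


# -- elementwise nonlinearities ---------------------------------------------


def exp(a):
    a = as_tensor(a)
    out = Tensor(np.exp(a.value))
    if _track(a):
        out.requires_grad = True
        out._parents = (a,)
        val = out.value  # captured by value: closures must not hold `out`
        out._backward = lambda g: a._accumulate(g * val)
    return out


def tanh(a):
    a = as_tensor(a)
    out = Tensor(np.tanh(a.value))
    if _track(a):
        out.requires_grad = True
        out._parents = (a,)
        val = out.value
        out._backward = lambda g: a._accumulate(g * (1.0 - val ** 2))
    return out


def relu(a):
    return _unary(a, lambda v: np.maximum(v, 0.0),
                  lambda g, v: g * (v > 0))


def absolute(a):
    return _unary(a, np.abs, lambda g, v: g * np.sign(v))


def clip(a, lo, hi):
    """Clamp values; gradient is zero where the clamp is active."""
    return _unary(a, lambda v: np.clip(v, lo, hi),
                  lambda g, v: g * ((v >= lo) & (v <= hi)))


def maximum_along(a, axis: int):
    """Max-reduce one axis; the adjoint routes to the (first) argmax."""
    a = as_tensor(a)
    idx = np.argmax(a.value, axis=axis)
    out_val = np.take_along_axis(a.value, np.expand_dims(idx, axis),
                                 axis=axis).squeeze(axis)
    out = Tensor(out_val)
    if _track(a):
        out.requires_grad = True
        out._parents = (a,)

        def bwd(g):
            full = np.zeros_like(a.value)
            np.put_along_axis(full, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            a._accumulate(full)

        out._backward = bwd
    return out


# -- gather / structural ops -------------------------------------------------


def _sl(axis: int, s: slice, ndim: int) -> tuple:
    out = [slice(None)] * ndim
    out[axis] = s
    return tuple(out)


def shift_axis(a, axis: int, k: int):
    """Edge-clamped shift along one axis: ``out[i] = in[clip(i + k)]``.

    Forward and adjoint are pure slicing (no scatter), which makes this
    the cheap primitive behind MIND patch distances and box sums.
    """
    a = as_tensor(a)
    if k == 0:
        return a
    n = a.value.shape[axis]
    idx = np.clip(np.arange(n) + k, 0, n - 1)
    out = Tensor(np.take(a.value, idx, axis=axis))
    if _track(a):
        out.requires_grad = True
        out._parents = (a,)
        nd = a.value.ndim
        m = min(abs(k), n - 1)

        def bwd(g):
            acc = np.zeros_like(a.value)
            if k > 0:
                acc[_sl(axis, slice(m, n), nd)] += g[_sl(axis, slice(0, n - m), nd)]
                acc[_sl(axis, slice(n - 1, n), nd)] += \
                    g[_sl(axis, slice(n - m, n), nd)].sum(axis=axis, keepdims=True)
            else:
                acc[_sl(axis, slice(0, n - m), nd)] += g[_sl(axis, slice(m, n), nd)]
                acc[_sl(axis, slice(0, 1), nd)] += \
                    g[_sl(axis, slice(0, m), nd)].sum(axis=axis, keepdims=True)
            a._accumulate(acc)

        out._backward = bwd
    return out


def take(a, flat_indices, out_shape=None):
    """Gather from the flattened array; adjoint is scatter-add (np.add.at)."""
    a = as_tensor(a)
    flat_indices = np.asarray(flat_indices)
    vals = a.value.reshape(-1)[flat_indices.reshape(-1)]
    shape = out_shape if out_shape is not None else flat_indices.shape
    out = Tensor(vals.reshape(shape))
    if _track(a):
        out.requires_grad = True
        out._parents = (a,)

        def bwd(g):
            acc = np.zeros(a.value.size, dtype=np.float64)
            np.add.at(acc, flat_indices.reshape(-1), g.reshape(-1))
            a._accumulate(acc.reshape(a.value.shape))

        out._backward = bwd
    return out


def pad_zero(a, pad_width):
    a = as_tensor(a)
    out = Tensor(np.pad(a.value, pad_width))
    if _track(a):
        out.requires_grad = True
        out._parents = (a,)
        slices = tuple(slice(lo, lo + s)
                       for (lo, _), s in zip(pad_width, a.value.shape))
        out._backward = lambda g: a._accumulate(g[slices])
    return out


def concatenate(tensors, axis: int = 0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis))
    if _track(*tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)
        sizes = [t.value.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = bwd
    return out


def stack(tensors, axis: int = 0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.value for t in tensors], axis=axis))
    if _track(*tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)

        def bwd(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accumulate(np.take(g, i, axis=axis))

        out._backward = bwd
    return out


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    if a.value.ndim != 2 or b.value.ndim != 2:
        raise ValueError("matmul supports 2D operands only")
    out = Tensor(a.value @ b.value)
    if _track(a, b):
        out.requires_grad = True
        out._parents = tuple(t for t in (a, b) if t.requires_grad)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g @ b.value.T)
            if b.requires_grad:
                b._accumulate(a.value.T @ g)

        out._backward = bwd
    return out
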