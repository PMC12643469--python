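"""Tape-based reverse-mode automatic differentiation on numpy arrays.

A minimal autodiff core supporting the operations the estimation network
needs: broadcasting arithmetic, matmul, reductions, cumulative sums, sigmoids,
concatenation and gather.  Vector-Jacobian products are themselves expressed
in terms of :class:`Tensor` operations, so ``grad(..., create_graph=True)``
yields a differentiable graph — this is what makes the WGAN gradient-penalty
term (a gradient norm that is itself differentiated during the critic update)
possible without an external deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "grad",
    "concatenate",
    "stack",
    "exp",
    "log",
    "tanh",
    "sigmoid",
    "sqrt",
    "absolute",
    "maximum_const",
    "cumsum",
    "matmul",
    "where_const",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "parents", "vjps", "requires_grad", "grad")
    __array_priority__ = 100.0  # numpy defers binary ops to Tensor

    def __init__(self, data, parents=(), vjps=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.vjps = vjps
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self.grad = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data)

    def numpy(self):
        return self.data

    def item(self):
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, n):
        return power(self, n)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, idx):
        return take(self, idx)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 0:
            axes = None
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    @property
    def T(self):
        return transpose(self, None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    ndim_extra = g.ndim - len(shape)
    if ndim_extra > 0:
        g = tsum(g, axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(g, b.shape),
        ),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data - b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(neg(g), b.shape),
        ),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(mul(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, a), b.shape),
        ),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data / b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(div(g, b), a.shape),
            lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, parents=(a,), vjps=(lambda g: neg(g),))


def power(a: Tensor, n) -> Tensor:
    n = float(n)
    return Tensor(
        a.data**n,
        parents=(a,),
        vjps=(lambda g: mul(g, mul(Tensor(n), power(a, n - 1.0))),),
    )


def exp(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(np.exp(a.data), parents=(a,))
    out.vjps = (lambda g: mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return Tensor(np.log(a.data), parents=(a,), vjps=(lambda g: div(g, a),))


def sqrt(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(np.sqrt(a.data), parents=(a,))
    out.vjps = (lambda g: div(g, mul(Tensor(2.0), out)),)
    return out


def tanh(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(np.tanh(a.data), parents=(a,))
    out.vjps = (lambda g: mul(g, sub(Tensor(1.0), mul(out, out))),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    with np.errstate(over="ignore"):
        val = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(val, parents=(a,))
    out.vjps = (lambda g: mul(g, mul(out, sub(Tensor(1.0), out))),)
    return out


def absolute(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    s = np.sign(a.data)
    return Tensor(np.abs(a.data), parents=(a,), vjps=(lambda g: mul(g, Tensor(s)),))


def maximum_const(a: Tensor, c: float) -> Tensor:
    """Elementwise max(a, c) for a constant c (ReLU-style)."""
    a = _as_tensor(a)
    m = (a.data > c).astype(np.float64)
    return Tensor(
        np.maximum(a.data, c), parents=(a,), vjps=(lambda g: mul(g, Tensor(m)),)
    )


def where_const(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select from a/b by a constant boolean mask (not differentiated w.r.t. cond)."""
    a, b = _as_tensor(a), _as_tensor(b)
    cond = np.asarray(cond)
    m = cond.astype(np.float64)
    return Tensor(
        np.where(cond, a.data, b.data),
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(mul(g, Tensor(m)), a.shape),
            lambda g: _unbroadcast(mul(g, Tensor(1.0 - m)), b.shape),
        ),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        vjps=(
            lambda g: matmul(g, transpose(b, None)),
            lambda g: matmul(transpose(a, None), g),
        ),
    )


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    in_shape = a.shape

    def vjp(g: Tensor) -> Tensor:
        gd = g
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            shp = list(g.shape)
            for ax in sorted(ax % len(in_shape) for ax in axes):
                shp.insert(ax, 1)
            gd = reshape(g, tuple(shp))
        return broadcast_to(gd, in_shape)

    return Tensor(out_data, parents=(a,), vjps=(vjp,))


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / float(n)))


def broadcast_to(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    if a.shape == tuple(shape):
        return a
    return Tensor(
        np.broadcast_to(a.data, shape).copy(),
        parents=(a,),
        vjps=(lambda g: _unbroadcast(g, a.shape),),
    )


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape
    return Tensor(
        a.data.reshape(shape), parents=(a,), vjps=(lambda g: reshape(g, old),)
    )


def transpose(a: Tensor, axes) -> Tensor:
    a = _as_tensor(a)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))
    return Tensor(
        a.data.transpose(axes) if axes is not None else a.data.T,
        parents=(a,),
        vjps=(lambda g: transpose(g, inv),),
    )


def take(a: Tensor, idx) -> Tensor:
    """Basic/advanced indexing with scatter-add backward."""
    a = _as_tensor(a)
    in_shape = a.shape

    def vjp(g: Tensor) -> Tensor:
        return _ScatterAdd(in_shape, idx)(g)

    return Tensor(a.data[idx], parents=(a,), vjps=(vjp,))


class _ScatterAdd:
    """Adjoint of indexing; itself linear, hence trivially re-differentiable."""

    def __init__(self, shape, idx):
        self.shape = shape
        self.idx = idx

    def __call__(self, g: Tensor) -> Tensor:
        shape, idx = self.shape, self.idx

        def vjp(gg: Tensor) -> Tensor:
            return take(gg, idx)

        out = np.zeros(shape, dtype=np.float64)
        np.add.at(out, idx, g.data)
        return Tensor(out, parents=(g,), vjps=(vjp,))


def cumsum(a: Tensor, axis: int) -> Tensor:
    a = _as_tensor(a)

    def vjp(g: Tensor) -> Tensor:
        return flip(cumsum(flip(g, axis), axis), axis)

    return Tensor(np.cumsum(a.data, axis=axis), parents=(a,), vjps=(vjp,))


def flip(a: Tensor, axis: int) -> Tensor:
    a = _as_tensor(a)
    return Tensor(
        np.flip(a.data, axis=axis).copy(),
        parents=(a,),
        vjps=(lambda g: flip(g, axis),),
    )


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g: Tensor) -> Tensor:
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return take(g, tuple(sl))

        return vjp

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        vjps=tuple(make_vjp(i) for i in range(len(tensors))),
    )


def stack(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def make_vjp(i):
        def vjp(g: Tensor) -> Tensor:
            sl = [slice(None)] * g.ndim
            sl[axis] = i
            return take(g, tuple(sl))

        return vjp

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        vjps=tuple(make_vjp(i) for i in range(len(tensors))),
    )


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
    stack_ = [(root, False)]
    while stack_:
        node, processed = stack_.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for p in node.parents:
            if id(p) not in seen and p.requires_grad:
                stack_.append((p, False))
    return order  # children before parents after reversal below


def grad(output: Tensor, inputs, grad_output=None, create_graph=False):
    """Gradients of a scalar (or seeded) output w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves graph
    nodes, enabling second-order terms such as the gradient penalty.
    """
    single = isinstance(inputs, Tensor)
    inputs_list = [inputs] if single else list(inputs)
    if grad_output is None:
        if output.size != 1:
            raise ValueError("grad of non-scalar output requires grad_output")
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): grad_output}

    for node in reversed(_toposort(output)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        node.grad = g
        for parent, vjp in zip(node.parents, node.vjps):
            if not parent.requires_grad:
                continue
            pg = vjp(g)
            if id(parent) in grads:
                grads[id(parent)] = add(grads[id(parent)], pg)
            else:
                grads[id(parent)] = pg

    out = []
    for t in inputs_list:
        g = t.grad if t.grad is not None else Tensor(np.zeros_like(t.data))
        if not create_graph:
            g = g.detach()
        out.append(g)
    # clear stored grads so repeated calls do not leak across graphs
    for node in _toposort(output):
        node.grad = None
    return out[0] if single else out
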