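"""Minimal reverse-mode automatic differentiation over numpy arrays.

The survival network in this package is small (a few hundred parameters per
module on the configurations used here), so a dynamic define-by-run graph of
numpy operations is fast enough on a single CPU and keeps every gradient
exactly inspectable.  The engine supports the operations the network needs —
broadcast arithmetic, matmul, the usual nonlinearities, reductions, reshapes,
concatenation and basic indexing — nothing more.

Gradients are accumulated into ``Tensor.grad`` by :func:`backward`, which
performs a topological sweep from a scalar root.  Float64 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "backward"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    for p in parents:
        if p.requires_grad:
            return Tensor(data, requires_grad=True, parents=parents, backward=backward)
    return Tensor(data)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        np.add(t.grad, g, out=t.grad)


# ------------------------------------------------------------------ primitives
def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bwd(g):
        g = np.asarray(g)
        if a.requires_grad:
            if b.data.ndim == 1 and a.data.ndim == 2:      # (n,k)@(k,) -> (n,)
                _accum(a, np.outer(g, b.data))
            elif b.data.ndim == 1:                          # (k,)@(k,) -> scalar
                _accum(a, g * b.data)
            elif a.data.ndim == 1:                          # (k,)@(k,m) -> (m,)
                _accum(a, g @ b.data.T)
            else:                                           # (n,k)@(k,m)
                _accum(a, g @ b.data.T)
        if b.requires_grad:
            if a.data.ndim == 1 and b.data.ndim == 2:
                _accum(b, np.outer(a.data, g))
            elif a.data.ndim == 1:
                _accum(b, g * a.data)
            elif b.data.ndim == 1:
                _accum(b, a.data.T @ g)
            else:
                _accum(b, a.data.T @ g)

    return _node(out_data, (a, b), bwd)


def bmm(a, b) -> Tensor:
    """Batched matmul over leading axes: (..., n, k) @ (..., k, m)."""
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            _accum(b, np.swapaxes(a.data, -1, -2) @ g)

    return _node(out_data, (a, b), bwd)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data ** p

    def bwd(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), bwd)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def bwd(g):
        _accum(a, g * out_data)

    return _node(out_data, (a,), bwd)


def log(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def bwd(g):
        _accum(a, g / a.data)

    return _node(out_data, (a,), bwd)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def tanh(a) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def bwd(g):
        _accum(a, g * (1.0 - out_data ** 2))

    return _node(out_data, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def bwd(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), bwd)


def silu(a) -> Tensor:
    """x * sigmoid(x) (the SiLU / swish activation)."""
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    out_data = a.data * s

    def bwd(g):
        _accum(a, g * (s + a.data * s * (1.0 - s)))

    return _node(out_data, (a,), bwd)


def softplus(a) -> Tensor:
    """log(1 + exp(x)), numerically stable for large |x|."""
    a = _wrap(a)
    out_data = np.logaddexp(0.0, a.data)

    def bwd(g):
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
        _accum(a, g * s)

    return _node(out_data, (a,), bwd)


def tensor_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _node(out_data, (a,), bwd)


def tensor_mean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def bwd(g):
        _accum(a, g.reshape(a.data.shape))

    return _node(out_data, (a,), bwd)


def transpose(a, axes=None) -> Tensor:
    a = _wrap(a)
    out_data = np.transpose(a.data, axes)

    def bwd(g):
        inv = None if axes is None else np.argsort(axes)
        _accum(a, np.transpose(g, inv))

    return _node(out_data, (a,), bwd)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _node(out_data, tuple(tensors), bwd)


def take(a, idx) -> Tensor:
    a = _wrap(a)
    out_data = a.data[idx]
    plain_slice = isinstance(idx, slice) or (
        isinstance(idx, tuple) and all(isinstance(s, slice) for s in idx)
    )

    def bwd(g):
        full = np.zeros_like(a.data)
        if plain_slice:
            full[idx] += g
        else:
            np.add.at(full, idx, g)
        _accum(a, full)

    return _node(out_data, (a,), bwd)


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    cond = np.asarray(cond, dtype=bool)
    out_data = np.where(cond, a.data, b.data)

    def bwd(g):
        _accum(a, _unbroadcast(np.where(cond, g, 0.0), a.data.shape))
        _accum(b, _unbroadcast(np.where(cond, 0.0, g), b.data.shape))

    return _node(out_data, (a, b), bwd)


# -------------------------------------------------------------- compositions
def softmax(a, axis=-1) -> Tensor:
    a = _wrap(a)
    shift = np.max(a.data, axis=axis, keepdims=True)  # constant: drops from grad
    e = exp(add(a, Tensor(-shift)))
    return mul(e, power(tensor_sum(e, axis=axis, keepdims=True), -1.0))


def logsumexp(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    shift = np.max(a.data, axis=axis, keepdims=True)
    e = exp(add(a, Tensor(-shift)))
    out = log(tensor_sum(e, axis=axis, keepdims=keepdims))
    if keepdims:
        shift_out = shift
    elif axis is None:
        shift_out = shift.reshape(())
    else:
        shift_out = np.squeeze(shift, axis=axis)
    return add(out, Tensor(shift_out))


# ------------------------------------------------------------------- backward
def backward(root: Tensor) -> None:
    """Backpropagate from a scalar `root`, accumulating into `.grad` fields."""
    if root.data.size != 1:
        raise ValueError("backward() requires a scalar root tensor")
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    root.grad = np.ones_like(root.data)
    for node in reversed(order):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
            # free graph references as we go; leaves keep their grads
            node._backward = None
            node._parents = ()
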