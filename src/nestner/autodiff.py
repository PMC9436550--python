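"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every operation builds a node holding
its inputs and a closure that pushes the output gradient back to them.
``Tensor.backward()`` runs the closures in reverse topological order.  All
arithmetic is float64.  The op set is exactly what the sequence encoder, the
biaffine span scorer and the boundary head need; each op's gradient is covered
by a central finite-difference check in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_grad_enabled: bool = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that numpy broadcasting introduced or stretched."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._children: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ meta
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -------------------------------------------------------------- backward
    def backward(self) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._children:
                if id(child) not in visited:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not part of the op set")
        return mul(self, 1.0 / float(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, children: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(c.requires_grad for c in children):
        out.requires_grad = True
        out._children = tuple(children)
        out._backward = backward
    return out


# ------------------------------------------------------------------ op zoo
def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward():
        a._accumulate(_unbroadcast(out.grad, a.shape))
        b._accumulate(_unbroadcast(out.grad, b.shape))

    out = _node(out_data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward():
        a._accumulate(_unbroadcast(out.grad * b.data, a.shape))
        b._accumulate(_unbroadcast(out.grad * a.data, b.shape))

    out = _node(out_data, (a, b), backward)
    return out


def matmul(a, b) -> Tensor:
    """Matrix product with numpy's stacked-batch semantics (ndim >= 2)."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward():
        a._accumulate(_unbroadcast(out.grad @ np.swapaxes(b.data, -1, -2), a.shape))
        b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ out.grad, b.shape))

    out = _node(out_data, (a, b), backward)
    return out


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    y = np.tanh(a.data)

    def backward():
        a._accumulate(out.grad * (1.0 - y * y))

    out = _node(y, (a,), backward)
    return out


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    x = a.data
    y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def backward():
        a._accumulate(out.grad * y * (1.0 - y))

    out = _node(y, (a,), backward)
    return out


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward():
        a._accumulate(out.grad * mask)

    out = _node(a.data * mask, (a,), backward)
    return out


def exp(a) -> Tensor:
    a = _as_tensor(a)
    y = np.exp(a.data)

    def backward():
        a._accumulate(out.grad * y)

    out = _node(y, (a,), backward)
    return out


def log(a) -> Tensor:
    a = _as_tensor(a)

    def backward():
        a._accumulate(out.grad / a.data)

    out = _node(np.log(a.data), (a,), backward)
    return out


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    out = _node(out_data, (a,), backward)
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def tmax(a, axis: int, keepdims=False) -> Tensor:
    """Max along one axis; gradient is split evenly among tied maxima."""
    a = _as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def backward():
        keep = out_data if keepdims else np.expand_dims(out_data, axis)
        mask = (a.data == keep).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        g = out.grad if keepdims else np.expand_dims(out.grad, axis)
        a._accumulate(mask * g)

    out = _node(out_data, (a,), backward)
    return out


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)

    def backward():
        a._accumulate(out.grad.reshape(a.shape))

    out = _node(a.data.reshape(shape), (a,), backward)
    return out


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    inv = np.argsort(axes)

    def backward():
        a._accumulate(out.grad.transpose(inv))

    out = _node(a.data.transpose(axes), (a,), backward)
    return out


def concat(tensors: Iterable, axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward():
        g = np.moveaxis(out.grad, axis, 0)
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            t._accumulate(np.moveaxis(g[lo:hi], 0, axis))

    out = _node(out_data, ts, backward)
    return out


def stack(tensors: Iterable, axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    expanded = [reshape(t, t.shape[:axis] + (1,) + t.shape[axis:]) for t in ts]
    return concat(expanded, axis=axis)


def getitem(a, idx) -> Tensor:
    """Indexing; supports basic slicing and integer-array (gather) indexing."""
    a = _as_tensor(a)
    out_data = a.data[idx]

    def backward():
        if a.grad is None:
            a.grad = np.zeros_like(a.data)
        np.add.at(a.grad, idx, out.grad)

    out = _node(out_data, (a,), backward)
    return out


def gather(a, index: np.ndarray, axis: int = -1) -> Tensor:
    """``np.take_along_axis``; one element picked per position along `axis`."""
    a = _as_tensor(a)
    out_data = np.take_along_axis(a.data, index, axis=axis)

    def backward():
        g = np.zeros_like(a.data)
        np.add.at(g, _along_axis_index(index, a.data.shape, axis), out.grad)
        a._accumulate(g)

    out = _node(out_data, (a,), backward)
    return out


def _along_axis_index(index: np.ndarray, shape: tuple[int, ...], axis: int):
    axis = axis % len(shape)
    grids = np.ogrid[tuple(slice(s) for s in index.shape)]
    return tuple(index if d == axis else grids[d] for d in range(len(shape)))


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    logits = shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))

    def backward():
        soft = np.exp(logits)
        a._accumulate(out.grad - soft * out.grad.sum(axis=axis, keepdims=True))

    out = _node(logits, (a,), backward)
    return out


def softmax(a, axis: int = -1) -> Tensor:
    return exp(log_softmax(a, axis=axis))


def embedding(table: Tensor, index: np.ndarray) -> Tensor:
    """Row lookup into an embedding table with scatter-add gradients."""
    index = np.asarray(index)
    out_data = table.data[index]

    def backward():
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, index, out.grad)

    out = _node(out_data, (table,), backward)
    return out
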