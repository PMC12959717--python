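"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it in a dynamically built DAG.  Calling :meth:`Tensor.backward` on a scalar
loss runs reverse accumulation through that graph.  Only the operations the
segmentation network needs are implemented; each op defines its forward
result and a closure that maps the output gradient to input gradients.

All arithmetic is float64 by default to keep gradient checks tight; the
training loop works equally in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- shape / dtype ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data.reshape(-1)[0])

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        s_shape, o_shape = self.data.shape, other.data.shape

        def backward(g):
            return _unbroadcast(g, s_shape), _unbroadcast(g, o_shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g / b.data, a.data.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent
        a = self

        def backward(g):
            return (g * exponent * a.data ** (exponent - 1),)

        return Tensor._make(out_data, (a,), backward)

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        a = self
        axes = axis

        def backward(g):
            if axes is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axes)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        a = self

        def backward(g):
            return (g.reshape(a.data.shape),)

        return Tensor._make(out_data, (a,), backward)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)
        a = self

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(out_data, (a,), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)
        a = self

        def backward(g):
            return (g * mask,)

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        a = self

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._make(out_data, (a,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        a = self

        def backward(g):
            return (g * out_data,)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        out_data = np.log(self.data)
        a = self

        def backward(g):
            return (g / a.data,)

        return Tensor._make(out_data, (a,), backward)

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out_data = self.data @ other.data
        a, b = self, other

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

        return Tensor._make(out_data, (a, b), backward)

    __matmul__ = matmul


def as_tensor(value) -> Tensor:
    if isinstance(value, Tensor):
        return value
    return Tensor(value)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient support."""
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
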