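"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ``ndarray`` and records, for every
differentiable operation, a closure that propagates the output gradient back
to the inputs.  ``Tensor.backward()`` runs these closures in reverse
topological order.  The op set is exactly what an encoder–decoder
segmentation network needs: broadcast arithmetic, matmul, reductions, shape
ops, pointwise nonlinearities, and (in :mod:`dnlseg.nn.functional`)
convolution, pooling and upsampling primitives.

Gradients are accumulated in ``float64`` throughout; determinism on a single
device follows from NumPy's deterministic kernels.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "concat", "stack", "as_tensor"]

# Global switch: inside `no_grad()` no graph is recorded (fast eval path).
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


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # Sum leading extra axes.
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # Sum axes that were 1 in the original shape.
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        # DFS postorder gives a valid topological order of the DAG.
        topo: list[Tensor] = []
        visited: set[int] = set()
        work: list[tuple[Tensor, bool]] = [(self, False)]
        while work:
            node, processed = work.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            work.append((node, True))
            for p in node._prev:
                if id(p) not in visited and (p._prev or p.requires_grad):
                    work.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # internal graph-node constructor -----------------------------------
    @staticmethod
    def _make(data: np.ndarray, prev: Sequence["Tensor"],
              backward: Callable[[np.ndarray], list] | None) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad or p._prev for p in prev):
            out._prev = tuple(prev)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            return [(a, _unbroadcast(g, a.data.shape)),
                    (b, _unbroadcast(g, b.data.shape))]

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self
        return Tensor._make(-a.data, (a,), lambda g: [(a, -g)])

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            return [(a, _unbroadcast(g * b.data, a.data.shape)),
                    (b, _unbroadcast(g * a.data, b.data.shape))]

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        a = self
        out_data = a.data ** exponent

        def backward(g):
            return [(a, g * exponent * a.data ** (exponent - 1.0))]

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return [(a, _unbroadcast(ga, a.data.shape)),
                    (b, _unbroadcast(gb, b.data.shape))]

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    # -------------------------------------------------------------- pointwise
    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: [(a, g * out_data)])

    def log(self) -> "Tensor":
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: [(a, g / a.data)])

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: [(a, g * mask)])

    def sigmoid(self) -> "Tensor":
        a = self
        d = a.data
        out_data = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                            np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))

        def backward(g):
            return [(a, g * out_data * (1.0 - out_data))]

        return Tensor._make(out_data, (a,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed only through unclipped entries."""
        a = self
        mask = (a.data > lo) & (a.data < hi)
        return Tensor._make(np.clip(a.data, lo, hi), (a,),
                            lambda g: [(a, g * mask)])

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return [(a, np.broadcast_to(g, a.data.shape).copy())]
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return [(a, np.broadcast_to(g, a.data.shape).copy())]

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: [(a, g.reshape(orig))])

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: [(a, g.transpose(inv))])

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        a = self
        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,),
                            lambda g: [(a, np.swapaxes(g, ax1, ax2))])

    # ----------------------------------------------------------- compositions
    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax along `axis`.

        The max-shift is treated as a constant; softmax is invariant to a
        per-row additive constant, so the gradient is unaffected.
        """
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)


class Parameter(Tensor):
    """A tensor that is a trainable parameter of a module."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return list(zip(ts, pieces))

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis),
                        tuple(ts), backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]

    def backward(g):
        pieces = np.split(g, len(ts), axis=axis)
        return [(t, np.squeeze(p, axis=axis)) for t, p in zip(ts, pieces)]

    return Tensor._make(np.stack([t.data for t in ts], axis=axis),
                        tuple(ts), backward)
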