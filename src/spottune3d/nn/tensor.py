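"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based autograd: every operation returns a new
:class:`Tensor` holding the result and a closure that accumulates gradients
into its parents. Only the operations the volumetric residual networks need
are implemented. Gradients are dense numpy arrays of the same dtype as the
data (float64 by default).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(data, np.ndarray) else data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()
        self.name = name

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- graph ops
    @staticmethod
    def _make(data, parents, backward):
        """Create a result tensor; attach the tape node only if needed."""
        track = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen and (p.requires_grad or p._parents):
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---------------------------------------------------------------- arith
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad or a._parents:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad or b._parents:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad or a._parents:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad or b._parents:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad or a._parents:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad or b._parents:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, self._coerce(other)

        def bwd(g):
            if a.requires_grad or a._parents:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad or b._parents:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    __matmul__ = matmul

    # ------------------------------------------------------------ elementwise
    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(np.where(mask, a.data, 0.0), (a,), bwd)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bwd)

    def exp(self) -> "Tensor":
        a = self
        e = np.exp(a.data)

        def bwd(g):
            a._accum(g * e)

        return Tensor._make(e, (a,), bwd)

    def log(self) -> "Tensor":
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy() if np.ndim(g) == 0 else np.full_like(a.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        n = a.data.size if axis is None else np.prod([a.data.shape[i] for i in np.atleast_1d(axis)])

        def bwd(g):
            if axis is None:
                a._accum(np.full_like(a.data, g / n))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg / n, a.data.shape).copy())

        return Tensor._make(a.data.mean(axis=axis, keepdims=keepdims), (a,), bwd)

    # ------------------------------------------------------------ structural
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bwd(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(a.data, axes), (a,), bwd)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

        return Tensor._make(s, (a,), bwd)
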