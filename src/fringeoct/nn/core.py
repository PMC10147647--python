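"""Minimal array-valued reverse-mode autodiff.

A small, dependency-free tape: each :class:`Tensor` wraps a numpy array and
remembers how to route gradients to its parents.  Only the operations the
enhancement networks and their training losses need are provided (elementwise
arithmetic, broadcasting, activations, 2-D convolution, batch
normalization, pooling, concatenation, reductions).  Gradients are
accumulated by a topological backward sweep from a scalar loss.

Float dtype follows the data: the networks run in float32, while metric
evaluation can pass float64 arrays through the same ops unchanged.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None or not p.requires_grad:
                    continue
                key = id(p)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- shape/props ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        """Wrap plain operands, keeping this tensor's float dtype so python
        scalars do not upcast a float32 graph to float64."""
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.shape),
                       _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.shape),
                       _unbroadcast(-g * self.data / other.data**2, other.shape)))

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        d = self.data

        def backward(g):
            # the derivative of x**w diverges at x=0 for w<1; route a zero
            # gradient there so downstream updates stay finite
            with np.errstate(divide="ignore", invalid="ignore"):
                gd = g * exponent * d**(exponent - 1.0)
            return (np.where(np.isfinite(gd), gd, 0.0),)

        return Tensor._make(d**exponent, (self,), backward)

    # -- elementwise functions --------------------------------------------
    def abs(self):
        s = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * s,))

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        d = self.data
        return Tensor._make(np.log(d), (self,), lambda g: (g / d,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,),
                            lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,),
                            lambda g: (g * mask,))

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        d = self.data

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, d.shape).astype(d.dtype),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, d.shape).astype(d.dtype),)

        return Tensor._make(d.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        d = self.data
        n = d.size if axis is None else np.prod(
            [d.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g / n, d.shape).astype(d.dtype),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg / n, d.shape).astype(d.dtype),)

        return Tensor._make(d.mean(axis=axis, keepdims=keepdims), (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: (g.reshape(old),))

    def __getitem__(self, key):
        d = self.data

        def backward(g):
            out = np.zeros_like(d)
            out[key] = g
            return (out,)

        return Tensor._make(d[key], (self,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)
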