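"""Minimal reverse-mode automatic differentiation on numpy arrays.

The autoencoders in this package are small dense networks (three hidden
layers at most), so a compact tape-based engine is sufficient: a
:class:`Tensor` wraps an ndarray, records its parents and a backward
closure, and :meth:`Tensor.backward` walks the tape in reverse
topological order.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand's shape.

Only the primitives the models need are provided (matmul, elementwise
arithmetic, reductions, transpose, concatenation, ``log``/``exp``,
``selu``/``softplus``, clipping).  Everything is float64 for
reproducibility across platforms.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "Adam"]

# SELU constants (Klambauer et al. self-normalizing networks)
_SELU_ALPHA = 1.6732632423543772848170429916717
_SELU_SCALE = 1.0507009873554804934193349852946


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph mechanics -------------------------------------------------
    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.value.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g * other.value)
            if other.requires_grad:
                other._accum(g * self.value)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.value / other.value, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g / other.value)
            if other.requires_grad:
                other._accum(-g * self.value / other.value**2)

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.value.T)
            if other.requires_grad:
                other._accum(self.value.T @ g)

        out._backward = back
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.value.T, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.T)
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise nonlinearities --------------------------------------
    def log(self) -> "Tensor":
        out = Tensor(np.log(self.value), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.value)
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.value), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.value)
        return out

    def square(self) -> "Tensor":
        return self * self

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient passes through only inside the bounds."""
        out = Tensor(np.clip(self.value, lo, hi), _parents=(self,))
        mask = (self.value > lo) & (self.value < hi)
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def selu(self) -> "Tensor":
        x = self.value
        pos = x > 0
        val = _SELU_SCALE * np.where(pos, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0))
        out = Tensor(val, _parents=(self,))
        deriv = _SELU_SCALE * np.where(pos, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))
        out._backward = lambda g: self.requires_grad and self._accum(g * deriv)
        return out

    def softplus(self) -> "Tensor":
        x = self.value
        val = np.logaddexp(0.0, x)
        out = Tensor(val, _parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-x))
        out._backward = lambda g: self.requires_grad and self._accum(g * sig)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``; gradients are split back."""
    values = [t.value for t in tensors]
    out = Tensor(np.concatenate(values, axis=axis), _parents=tuple(tensors))
    sizes = [v.shape[axis] for v in values]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out._backward = back
    return out


def softmax(logits: Tensor) -> Tensor:
    """Row-wise softmax (numerically stabilised by the detached row max)."""
    shift = logits - Tensor(logits.value.max(axis=1, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer over a list of :class:`Tensor` parameters."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}
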