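"""Tape-based reverse-mode automatic differentiation on numpy arrays.

The model family in this package (tabular Q-learners and small recurrent
networks, unrolled over 150-trial blocks) needs gradients of a scalar
negative log-likelihood with respect to a few dozen parameter arrays.  This
module provides exactly that: a :class:`Tensor` wrapping an ``ndarray``, a
closed set of differentiable primitives (arithmetic, matmul, tanh, sigmoid,
softplus, abs, concat, reductions, logsumexp), and :meth:`Tensor.backward`,
which accumulates gradients by reverse topological traversal.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back down to the operand's shape.  All primitives are gradient-checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: an array plus backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        if type(data) is not np.ndarray or data.dtype != np.float64:
            data = np.asarray(data, dtype=np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        if not requires_grad:
            for p in parents:
                if p.requires_grad:
                    requires_grad = True
                    break
        self.requires_grad = requires_grad
        self._parents = parents if requires_grad else ()
        self._backward = backward if requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph traversal -------------------------------------------------

    def backward(self) -> None:
        """Accumulate gradients of ``self`` (a scalar) into ``.grad`` fields."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- primitives ------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g)
                if b.requires_grad:
                    b._accum(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        other = _wrap(other)
        out = Tensor(self.data - other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g)
                if b.requires_grad:
                    b._accum(-g)
            out._backward = backward
        return out

    def __rsub__(self, other):
        return _wrap(other).__sub__(self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g * b.data)
                if b.requires_grad:
                    b._accum(g * a.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g / b.data)
                if b.requires_grad:
                    b._accum(-g * a.data / b.data**2)
            out._backward = backward
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g @ b.data.swapaxes(-1, -2))
                if b.requires_grad:
                    b._accum(a.data.swapaxes(-1, -2) @ g)
            out._backward = backward
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * y * (1.0 - y))
        return out

    def softplus(self):
        # log(1 + e^x), computed stably
        y = np.logaddexp(0.0, self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            s = 1.0 / (1.0 + np.exp(-self.data))
            out._backward = lambda g, a=self, s=s: a._accum(g * s)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))
        if out.requires_grad:
            sign = np.sign(self.data)
            out._backward = lambda g, a=self, sign=sign: a._accum(g * sign)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape))
            out._backward = backward
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    """Create a leaf tensor."""
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g, parts=tensors, splits=splits, axis=axis):
            for part, grad in zip(parts, np.split(g, splits, axis=axis)):
                if part.requires_grad:
                    part._accum(grad)
        out._backward = backward
    return out


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` (differentiable)."""
    m = x.data.max(axis=axis, keepdims=True)
    y = m + np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True))
    out_data = y if keepdims else np.squeeze(y, axis=axis)
    out = Tensor(out_data, parents=(x,))
    if out.requires_grad:
        soft = np.exp(x.data - y)  # softmax along axis

        def backward(g, a=x, soft=soft, axis=axis, keepdims=keepdims):
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(g * soft)
        out._backward = backward
    return out
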