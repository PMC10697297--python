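"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are tiny (a bidirectional LSTM with 5 hidden
units, a 10->5 condensing layer and a 5->2->1 regressor), so a small
tape-based engine over numpy is sufficient and keeps the whole training
stack self-contained and deterministic.  Only the operations the model
graphs actually use are implemented.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        # Always copy on first write: the incoming array may be shared with
        # (or be a view of) another node's gradient, and later accumulation
        # is in-place.
        if self.grad is None:
            self.grad = np.array(grad)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(stack_.pop())
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(grad):
            a._accumulate(_unbroadcast(grad, a.data.shape))
            b._accumulate(_unbroadcast(grad, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(grad):
            a._accumulate(-grad)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(grad):
            a._accumulate(_unbroadcast(grad * b.data, a.data.shape))
            b._accumulate(_unbroadcast(grad * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(grad):
            a._accumulate(grad @ b.data.T)
            b._accumulate(a.data.T @ grad)

        return self._make(a.data @ b.data, (a, b), backward)

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def backward(grad):
            a._accumulate(grad * p * a.data ** (p - 1.0))

        return self._make(a.data ** p, (a,), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(grad):
            a._accumulate(grad * mask)

        return self._make(a.data * mask, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(grad):
            a._accumulate(grad * (1.0 - out_data ** 2))

        return self._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(grad):
            a._accumulate(grad * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    # -- shape ops ---------------------------------------------------------

    def __getitem__(self, key):
        a = self

        def backward(grad):
            full = np.zeros_like(a.data)
            np.add.at(full, key, grad)
            a._accumulate(full)

        return self._make(a.data[key], (a,), backward)

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(grad):
            a._accumulate(grad.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list, axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * grad.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(idx)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._parents for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list, axis: int = 0) -> Tensor:
    """Stack tensors along a new axis."""
    tensors = [Tensor._lift(t) for t in tensors]

    def backward(grad):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(grad, i, axis=axis))

    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._parents for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


class Adam:
    """Adaptive-moment optimizer (standard bias-corrected form) with
    optional global-norm gradient clipping (recurrent nets unrolled through
    an autoregressive feedback occasionally produce exploding gradients)."""

    def __init__(self, params: list, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.clip_norm = clip_norm
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _clip(self) -> None:
        if self.clip_norm is None:
            return
        total = np.sqrt(sum(float(np.sum(p.grad ** 2))
                            for p in self.params if p.grad is not None))
        if total > self.clip_norm:
            scale = self.clip_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self) -> None:
        self._clip()
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            m_hat = m / (1.0 - b1 ** self.t)
            v_hat = v / (1.0 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
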