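"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the generative / recognition networks and the
evidence-lower-bound graph need: broadcasting arithmetic, matmul, pointwise
nonlinearities, reductions, log-sum-exp / softmax, row gather, concatenation,
and a custom block-bidiagonal triangular solve (defined in ``inference``).

All arrays are float64.  Gradients accumulate into ``Tensor.grad`` after
calling ``backward()`` on a scalar output.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "concat", "gather_rows", "custom_op"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # ---------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            return (g @ other.data.T, self.data.T @ g)
        out._backward = bw
        return out

    # --------------------------------------------------------- nonlinearities
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * 0.5 / val,)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * (1.0 - val ** 2),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g * sign,)
        return out

    def softplus(self):
        # log(1 + e^x), numerically stable
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, self.requires_grad, (self,))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda g: (g * sig,)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        val = (m + np.log(s)).squeeze(axis)
        soft = np.exp(self.data - m) / s
        out = Tensor(val, self.requires_grad, (self,))

        def bw(g):
            return (np.expand_dims(np.asarray(g), axis) * soft,)
        out._backward = bw
        return out

    def softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        val = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(val, self.requires_grad, (self,))

        def bw(g):
            dot = (g * val).sum(axis=axis, keepdims=True)
            return ((g - dot) * val,)
        out._backward = bw
        return out

    # ------------------------------------------------------------- structural
    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)
        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    # ---------------------------------------------------------------- backward
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS; goal paths make graphs deep-ish
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))

        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.get(id(t))
            if g is None:
                continue
            if t._backward is not None and t._parents:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = np.asarray(pg, dtype=np.float64)
            else:
                # leaf
                if t.grad is None:
                    t.grad = np.array(g, dtype=np.float64, copy=True)
                else:
                    t.grad = t.grad + g


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))
    out._backward = bw
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``t[idx]``; backward scatter-adds."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], t.requires_grad, (t,))

    def bw(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        return (full,)
    out._backward = bw
    return out


def custom_op(parents, value: np.ndarray, vjp) -> Tensor:
    """Build a Tensor from a hand-written forward value and VJP.

    ``vjp(g)`` must return one cotangent per parent (None allowed).
    """
    parents = tuple(astensor(p) for p in parents)
    out = Tensor(value, any(p.requires_grad for p in parents), parents)
    out._backward = vjp
    return out
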