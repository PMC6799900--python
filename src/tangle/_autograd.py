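"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the recurrent attention models need:
broadcasting arithmetic, (batched) matmul, the usual activations, axis
reductions, concatenation, slicing, embedding-row gather and dropout.
Gradients are accumulated by topological-order backpropagation; every
op is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "matmul",
    "tanh",
    "sigmoid",
    "relu",
    "exp",
    "log",
    "clip",
    "concat",
    "stack",
    "embedding",
    "dropout",
    "masked_softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- graph mechanics ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- operators ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        out._backward = back
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = back
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = back
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        out._backward = back
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        # treated as a constant w.r.t. gradients (used for softmax shifting)
        return Tensor(self.data.max(axis=axis, keepdims=keepdims))

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def back(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2) if b.data.ndim > 1 else np.outer(g, b.data)
            a._accum(ga)
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g if a.data.ndim > 1 else np.outer(a.data, g)
            b._accum(gb)

    out._backward = back
    return out


def _unary(x, fn, dfn):
    x = as_tensor(x)
    y = fn(x.data)
    out = Tensor(y, parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accum(g * dfn(x.data, y))

    out._backward = back
    return out


def tanh(x):
    return _unary(x, np.tanh, lambda d, y: 1.0 - y ** 2)


def sigmoid(x):
    def fwd(d):
        out = np.empty_like(d)
        pos = d >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    return _unary(x, fwd, lambda d, y: y * (1.0 - y))


def relu(x):
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda d, y: (d > 0).astype(float))


def exp(x):
    return _unary(x, np.exp, lambda d, y: y)


def log(x):
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def clip(x, lo, hi):
    """Clamp values; gradient flows only through the un-clipped region."""
    return _unary(
        x,
        lambda d: np.clip(d, lo, hi),
        lambda d, y: ((d > lo) & (d < hi)).astype(float),
    )


def concat(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = back
    return out


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def back(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = back
    return out


def embedding(weights: Tensor, indices: np.ndarray):
    """Gather rows of `weights` (V+1, E) by an integer index array."""
    weights = as_tensor(weights)
    idx = np.asarray(indices)
    if idx.min() < 0 or idx.max() >= weights.data.shape[0]:
        raise IndexError(
            f"embedding index out of range [0, {weights.data.shape[0] - 1}]"
        )
    out = Tensor(weights.data[idx], parents=(weights,))

    def back(g):
        if weights.requires_grad:
            full = np.zeros_like(weights.data)
            np.add.at(full, idx.ravel(), g.reshape(-1, g.shape[-1]))
            weights._accum(full)

    out._backward = back
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator):
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return as_tensor(x)
    keep = (rng.random(as_tensor(x).shape) >= rate) / (1.0 - rate)
    return as_tensor(x) * Tensor(keep)


def masked_softmax(logits: Tensor, mask: np.ndarray, axis: int):
    """Softmax along `axis` restricted to positions where mask is True.

    Masked positions receive probability exactly 0. mask broadcasts
    against logits.
    """
    logits = as_tensor(logits)
    m = np.broadcast_to(np.asarray(mask, dtype=bool), logits.shape)
    if not m.any(axis=axis).all():
        raise ValueError("masked_softmax: at least one position per slice must be unmasked")
    neg = Tensor(np.where(m, 0.0, -1e30))
    shifted = logits + neg
    shifted = shifted - shifted.max(axis=axis, keepdims=True)
    e = exp(shifted) * Tensor(m.astype(float))
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
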