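"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the node-classification models need:
dense/sparse matrix products, broadcast arithmetic, ReLU, exp/log,
row-wise log-softmax, row gathering, concatenation and reductions.
Graphs are built eagerly; ``Tensor.backward()`` runs a topological
sweep accumulating ``.grad`` on every tensor with ``requires_grad``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "as_tensor", "spmm", "concat", "nll_loss", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.T)

        return self._make(self.data.T, (self,), backward)

    # -- nonlinearities & reductions ------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def log_softmax(self) -> "Tensor":
        """Row-wise log-softmax (numerically stabilised)."""
        x = self.data
        m = x.max(axis=1, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        out_data = z - lse
        softmax = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g - softmax * g.sum(axis=1, keepdims=True))

        return self._make(out_data, (self,), backward)

    def rows(self, idx) -> "Tensor":
        """Gather a subset of rows; gradient scatter-adds back."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return self._make(self.data[idx], (self,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def spmm(a, h: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a dense tensor."""
    h = as_tensor(h)
    a = sp.csr_array(a)

    def backward(g):
        if h.requires_grad:
            h._accumulate(a.T @ g)

    return h._make(a @ h.data, (h,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def nll_loss(log_probs: Tensor, targets) -> Tensor:
    """Mean negative log-likelihood of integer ``targets`` under row log-probs."""
    targets = np.asarray(targets, dtype=np.intp)
    n = log_probs.shape[0]
    if targets.shape[0] != n:
        raise ValueError("targets length must match number of rows")
    picked = log_probs.data[np.arange(n), targets]

    def backward(g):
        if log_probs.requires_grad:
            full = np.zeros_like(log_probs.data)
            full[np.arange(n), targets] = -g / n
            log_probs._accumulate(full)

    return log_probs._make(np.array(-picked.mean()), (log_probs,), backward)


class AdamW:
    """AdamW with decoupled weight decay on a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-4,
                 weight_decay=5e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            p.data *= 1.0 - self.lr * self.weight_decay
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
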