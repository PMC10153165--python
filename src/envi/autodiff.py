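"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the variational model needs: affine maps,
elementwise arithmetic, exp/log/softplus/sigmoid/relu, log-gamma (gradient
via the digamma function), reductions, slicing and concatenation. Gradients
of broadcast operations are un-broadcast by summation, matching the usual
convention. Nodes form a DAG; ``backward`` runs a topological sweep.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln as _gammaln_np


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
        if g.shape == tuple(shape):
            return g
        extra = g.ndim - len(shape)
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    self._unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            self._accumulate(g * val)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bwd(g):
            self._accumulate(g * mask)

        out._backward = bwd
        return out

    def softplus(self):
        # overflow-safe log(1 + exp(x))
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * sig)

        out._backward = bwd
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(val, parents=(self,))

        def bwd(g):
            self._accumulate(g * val * (1.0 - val))

        out._backward = bwd
        return out

    def gammaln(self):
        out = Tensor(_gammaln_np(self.data), parents=(self,))

        def bwd(g):
            self._accumulate(g * digamma(self.data))

        out._backward = bwd
        return out

    # -- shape ops ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            self._accumulate(g.reshape(self.shape))

        out._backward = bwd
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = bwd
        return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = bwd
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """ADAM optimizer over a flat list of Parameters."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
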