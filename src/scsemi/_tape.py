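"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape engine sufficient for the losses in this package: dense layers,
elementwise nonlinearities, log-gamma terms of the ZINB likelihood, and the
gather/normalize operations of the clustering and constraint losses. All
values are float64 for reproducibility. Not a general autodiff framework.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, digamma


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the computation graph.

    Leaves with ``requires_grad=True`` accumulate gradients in ``.grad``
    after :func:`backward` is called on a scalar result.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_grad_fns")

    def __init__(self, value, requires_grad: bool = False,
                 parents=(), grad_fns=()):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._grad_fns = grad_fns

    @property
    def shape(self):
        return self.value.shape

    # convenience operators
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(value, parents, grad_fns) -> Tensor:
    # drop the graph when no parent needs gradients
    if not any(p.requires_grad for p in parents):
        return Tensor(value)
    return Tensor(value, parents=parents, grad_fns=grad_fns)


def backward(result: Tensor) -> None:
    """Backpropagate from a scalar `result` through the tape."""
    if result.value.size != 1:
        raise ValueError("backward() requires a scalar result")
    topo, seen = [], set()

    def visit(node):
        if id(node) in seen or not node.requires_grad:
            return
        seen.add(id(node))
        for p in node._parents:
            visit(p)
        topo.append(node)

    visit(result)
    for node in topo:
        node.grad = np.zeros_like(node.value)
    result.grad = np.ones_like(result.value)
    for node in reversed(topo):
        g = node.grad
        for parent, fn in zip(node._parents, node._grad_fns):
            if parent.requires_grad and fn is not None:
                parent.grad = parent.grad + _unbroadcast(fn(g), parent.value.shape)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.value + b.value, (a, b), (lambda g: g, lambda g: g))


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.value - b.value, (a, b), (lambda g: g, lambda g: -g))


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.value * b.value, (a, b),
                 (lambda g: g * b.value, lambda g: g * a.value))


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.value / b.value, (a, b),
                 (lambda g: g / b.value,
                  lambda g: -g * a.value / (b.value ** 2)))


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.value @ b.value, (a, b),
                 (lambda g: g @ b.value.T, lambda g: a.value.T @ g))


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)

    def grad(g):
        if axis is None:
            return np.broadcast_to(g, a.value.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.value.shape).copy()

    return _make(a.value.sum(axis=axis, keepdims=keepdims), (a,), (grad,))


def tmean(a):
    a = as_tensor(a)
    n = a.value.size
    return _make(a.value.mean(), (a,),
                 (lambda g: np.broadcast_to(g / n, a.value.shape).copy(),))


def relu(a):
    a = as_tensor(a)
    mask = a.value > 0
    return _make(np.where(mask, a.value, 0.0), (a,), (lambda g: g * mask,))


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.value)
    return _make(out, (a,), (lambda g: g * out,))


def log(a):
    a = as_tensor(a)
    return _make(np.log(a.value), (a,), (lambda g: g / a.value,))


def power(a, c: float):
    a = as_tensor(a)
    return _make(a.value ** c, (a,),
                 (lambda g: g * c * a.value ** (c - 1.0),))


def sqrt(a):
    return power(a, 0.5)


def softplus(a):
    """log(1 + exp(a)), computed stably; gradient is the logistic function."""
    a = as_tensor(a)
    out = np.logaddexp(0.0, a.value)
    sig = 1.0 / (1.0 + np.exp(-a.value))
    return _make(out, (a,), (lambda g: g * sig,))


def lgamma(a):
    a = as_tensor(a)
    return _make(gammaln(a.value), (a,),
                 (lambda g: g * digamma(a.value),))


def maximum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    mask = a.value >= b.value
    return _make(np.where(mask, a.value, b.value), (a, b),
                 (lambda g: g * mask, lambda g: g * ~mask))


def clip(a, lo: float, hi: float):
    """Hard clip; gradient passes only inside the interval."""
    a = as_tensor(a)
    mask = (a.value > lo) & (a.value < hi)
    return _make(np.clip(a.value, lo, hi), (a,), (lambda g: g * mask,))


def take_rows(a, idx):
    a = as_tensor(a)
    idx = np.asarray(idx)

    def grad(g):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return out

    return _make(a.value[idx], (a,), (grad,))


def take_cols(a, idx):
    a = as_tensor(a)
    idx = np.asarray(idx)

    def grad(g):
        out = np.zeros_like(a.value)
        np.add.at(out.T, idx, g.T)
        return out

    return _make(a.value[:, idx], (a,), (grad,))


def logsumexp2(a, b):
    """Elementwise log(exp(a) + exp(b)), overflow-safe."""
    m = maximum(a, b)
    return m + log(exp(a - m) + exp(b - m) + 1e-300)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdaDelta:
    """AdaDelta with per-parameter running averages of squared gradients
    and squared updates (Zeiler's scheme with an explicit learning rate)."""

    def __init__(self, params: list[Tensor], lr: float = 1.0,
                 rho: float = 0.9, eps: float = 1e-6):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._eg2 = [np.zeros_like(p.value) for p in params]
        self._ed2 = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, eg2, ed2 in zip(self.params, self._eg2, self._ed2):
            if p.grad is None:
                continue
            g = p.grad
            eg2 *= self.rho
            eg2 += (1.0 - self.rho) * g * g
            delta = -np.sqrt((ed2 + self.eps) / (eg2 + self.eps)) * g
            ed2 *= self.rho
            ed2 += (1.0 - self.rho) * delta * delta
            p.value = p.value + self.lr * delta

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
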