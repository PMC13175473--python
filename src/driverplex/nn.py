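"""Minimal tape-based reverse-mode automatic differentiation over numpy.

Implements exactly the operations the encoders and losses in this package
need: dense/broadcast arithmetic, dense matmul, products with constant
scipy.sparse operators, row gathering with scatter-add gradients (used for
degree-embedding lookups and labeled-node losses), stable log-sigmoid and
log-softmax, dropout, and an AdamW optimizer.  All graphs here have a few
hundred to a few thousand nodes, so full-batch numpy training is fast.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "matmul",
    "spmm",
    "take_rows",
    "relu",
    "exp",
    "log",
    "sqrt",
    "logsigmoid",
    "sigmoid",
    "log_softmax",
    "softmax",
    "dropout",
    "l2_normalize_rows",
    "AdamW",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        if isinstance(data, np.ndarray) and data.dtype == np.float64:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = parents

    # -- basic protocol -------------------------------------------------
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

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = ensure_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g)
                if other.requires_grad:
                    other._accumulate(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-ensure_tensor(other))

    def __rsub__(self, other):
        return ensure_tensor(other) + (-self)

    def __mul__(self, other):
        other = ensure_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g * other.data)
                if other.requires_grad:
                    other._accumulate(g * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = ensure_tensor(other)
        out = _node(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g / other.data)
                if other.requires_grad:
                    other._accumulate(-g * self.data / other.data ** 2)
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return ensure_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g):
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = _node(self.data.T, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.T)
        return out


def _node(data, parents) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad))


def ensure_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


# -- linear algebra -----------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = ensure_tensor(a), ensure_tensor(b)
    out = _node(a.data @ b.data, (a, b))
    if out.requires_grad:
        def bw(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)
        out._backward = bw
    return out


def spmm(s: sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a constant sparse operator with a dense tensor."""
    x = ensure_tensor(x)
    out = _node(s @ x.data, (x,))
    if out.requires_grad:
        st = getattr(s, "_spmm_t_cache", None)
        if st is None:
            st = s.T.tocsr()
            try:
                s._spmm_t_cache = st
            except AttributeError:  # pragma: no cover - exotic sparse types
                pass
        out._backward = lambda g: x._accumulate(st @ g)
    return out


def take_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows; gradient scatter-adds (supports repeated indices)."""
    idx = np.asarray(idx, dtype=np.intp)
    out = _node(t.data[idx], (t,))
    if out.requires_grad:
        def bw(g):
            full = np.zeros_like(t.data)
            np.add.at(full, idx, g)
            t._accumulate(full)
        out._backward = bw
    return out


# -- nonlinearities and stable log-domain ops ---------------------------

def relu(x: Tensor) -> Tensor:
    x = ensure_tensor(x)
    out = _node(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def exp(x: Tensor) -> Tensor:
    x = ensure_tensor(x)
    out = _node(np.exp(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * out.data)
    return out


def log(x: Tensor) -> Tensor:
    x = ensure_tensor(x)
    out = _node(np.log(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    return x ** 0.5


def logsigmoid(x: Tensor) -> Tensor:
    """log(sigma(x)) = -softplus(-x), evaluated without overflow."""
    x = ensure_tensor(x)
    v = np.where(x.data >= 0, -np.log1p(np.exp(-np.abs(x.data))),
                 x.data - np.log1p(np.exp(-np.abs(x.data))))
    out = _node(v, (x,))
    if out.requires_grad:
        sig = 1.0 / (1.0 + np.exp(-np.abs(x.data)))
        # sigmoid(-x), stable for either sign
        sneg = np.where(x.data >= 0, 1.0 - sig, sig)
        out._backward = lambda g: x._accumulate(g * sneg)
    return out


def sigmoid(x: Tensor) -> Tensor:
    return exp(logsigmoid(x))


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = ensure_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True)) + m
    out = _node(x.data - lse, (x,))
    if out.requires_grad:
        def bw(g):
            sm = np.exp(out.data)
            x._accumulate(g - sm * g.sum(axis=axis, keepdims=True))
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(x, axis=axis))


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; caller decides whether training is active."""
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return x * Tensor(mask)


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    nrm = sqrt((x * x).sum(axis=1, keepdims=True) + Tensor(eps))
    return x / nrm


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            if self.wd:
                p.data -= self.lr * self.wd * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
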