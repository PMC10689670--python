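"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The policy networks here are tiny (a few thousand parameters), so instead of
pulling in a deep-learning framework we differentiate through a small tape of
array operations.  Gradients are checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "relu", "softmax", "layer_norm", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def backward(self):
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not (t.requires_grad or t._prev):
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad = self.grad + np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- ops ----------------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            if self.grad is not None:
                self.grad += _unbroadcast(out.grad, self.data.shape)
            if other.grad is not None:
                other.grad += _unbroadcast(out.grad, other.data.shape)

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.grad is not None:
                self.grad += -out.grad

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward():
            if self.grad is not None:
                self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            if other.grad is not None:
                other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out = self._make(self.data * other.data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward():
            if self.grad is not None:
                self.grad += _unbroadcast(out.grad / other.data, self.data.shape)
            if other.grad is not None:
                other.grad += _unbroadcast(
                    -out.grad * self.data / other.data**2, other.data.shape
                )

        out = self._make(self.data / other.data, (self, other), backward)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward():
            if self.grad is not None:
                self.grad += out.grad @ other.data.T
            if other.grad is not None:
                other.grad += self.data.T @ out.grad

        out = self._make(self.data @ other.data, (self, other), backward)
        return out

    def __getitem__(self, key):
        def backward():
            if self.grad is not None:
                np.add.at(self.grad, key, out.grad)

        out = self._make(self.data[key], (self,), backward)
        return out

    def sum(self, axis=None, keepdims=False):
        def backward():
            if self.grad is None:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.data.shape)

        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def exp(self):
        def backward():
            if self.grad is not None:
                self.grad += out.grad * out.data

        out = self._make(np.exp(self.data), (self,), backward)
        return out

    def log(self):
        def backward():
            if self.grad is not None:
                self.grad += out.grad / self.data

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def sqrt(self):
        def backward():
            if self.grad is not None:
                self.grad += out.grad * 0.5 / out.data

        out = self._make(np.sqrt(self.data), (self,), backward)
        return out

    def __pow__(self, p: float):
        def backward():
            if self.grad is not None:
                self.grad += out.grad * p * self.data ** (p - 1)

        out = self._make(self.data**p, (self,), backward)
        return out

    def reshape(self, *shape):
        def backward():
            if self.grad is not None:
                self.grad += out.grad.reshape(self.data.shape)

        out = self._make(self.data.reshape(*shape), (self,), backward)
        return out

    @property
    def T(self):
        def backward():
            if self.grad is not None:
                self.grad += out.grad.T

        out = self._make(self.data.T, (self,), backward)
        return out


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)
    return x * Tensor(mask)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by the (constant) row max for numerical stability
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Per-row layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad or t._prev for t in tensors):
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.grad is not None:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(lo, hi)
                    t.grad += out.grad[tuple(sl)]

        out._prev = tuple(tensors)
        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a dict of parameter Tensors.

    ``lr_overrides`` maps parameter-name prefixes to alternative learning
    rates (used to give the critic head its own rate).
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 3e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 lr_overrides: dict[str, float] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_overrides = lr_overrides or {}
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def _lr_for(self, name: str) -> float:
        for prefix, lr in self.lr_overrides.items():
            if name.startswith(prefix):
                return lr
        return self.lr

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient in {k}")
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self._lr_for(k) * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
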