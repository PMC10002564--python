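"""Minimal reverse-mode automatic differentiation on numpy arrays.

The drug-pair model (channel networks, attention fusion, graph encoders)
needs gradients through compositions of matmuls, convolutions, softmax
attention and normalization layers.  This module provides exactly the
primitives those layers use — a :class:`Tensor` wrapping an ndarray plus a
tape-free DAG backward pass — and a generic Adam optimizer.  It is not a
general deep-learning framework: only the operations required by the model
are implemented, each with an analytic gradient.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Adam",
    "concat",
    "cross_entropy",
]

_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in a backward-differentiable computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in _parents)
        self._parents = _parents if self.requires_grad else ()

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            g = node.grad
            for parent, grad_fn in node._parents:
                if not parent.requires_grad:
                    continue
                pg = grad_fn(g)
                if parent.grad is None:
                    parent.grad = pg.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            # scalar fast path: a builtin scalar is "weak" so the dtype is
            # kept, and no constant graph node is built (numpy float64
            # scalars subclass float but are strong — coerce them)
            other = other if type(other) is int else float(other)
            return Tensor(self.data + other, _parents=((self, lambda g: g),))
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            scalar = other if type(other) is int else float(other)
            return Tensor(self.data * scalar,
                          _parents=((self, lambda g: g * scalar),))
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data * other.data), other.shape
                    ),
                ),
            ),
        )

    def __pow__(self, exponent: float):
        out = self.data**exponent
        return Tensor(
            out,
            _parents=(
                (self, lambda g: g * exponent * self.data ** (exponent - 1)),
            ),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor(
            a @ b,
            _parents=(
                (self, lambda g: _unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape)),
                (other, lambda g: _unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape)),
            ),
        )

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return Tensor(
            self.data.reshape(*shape),
            _parents=((self, lambda g: g.reshape(old)),),
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            _parents=((self, lambda g: g.transpose(inv)),),
        )

    def narrow(self, axis: int, start: int, length: int):
        """Slice ``[start, start+length)`` along ``axis``."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def grad_fn(g):
            full = np.zeros(self.shape, dtype=g.dtype)
            full[idx] = g
            return full

        return Tensor(self.data[idx], _parents=((self, grad_fn),))

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad along one axis."""
        widths = [(0, 0)] * self.ndim
        widths[axis] = (before, after)
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(before, before + self.shape[axis])
        idx = tuple(idx)
        return Tensor(
            np.pad(self.data, widths),
            _parents=((self, lambda g: g[idx]),),
        )

    def gather_rows(self, index: np.ndarray):
        """Select rows along axis 0 (embedding-style lookup)."""
        index = np.asarray(index)

        def grad_fn(g):
            full = np.zeros(self.shape, dtype=g.dtype)
            np.add.at(full, index, g)
            return full

        return Tensor(self.data[index], _parents=((self, grad_fn),))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            gk = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gk, self.shape).copy()

        return Tensor(out, _parents=((self, grad_fn),))

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        arg = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(arg, axis), axis=axis)

        def grad_fn(g):
            gk = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros(self.shape, dtype=g.dtype)
            np.put_along_axis(full, np.expand_dims(arg, axis), gk, axis=axis)
            return full

        out = out if keepdims else out.squeeze(axis)
        return Tensor(out, _parents=((self, grad_fn),))

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, _parents=((self, lambda g: g * out),))

    def log(self):
        return Tensor(
            np.log(self.data), _parents=((self, lambda g: g / self.data),)
        )

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, _parents=((self, lambda g: g * (1.0 - out * out)),))

    def leaky_relu(self, negative_slope: float = 0.01):
        slope = np.where(self.data > 0, 1.0, negative_slope).astype(self.data.dtype)
        return Tensor(self.data * slope, _parents=((self, lambda g: g * slope),))

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        out = x * phi
        dens = np.exp(-0.5 * x * x) * _INV_SQRT_2PI
        return Tensor(out, _parents=((self, lambda g: g * (phi + x * dens)),))

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def grad_fn(g):
            return out * (g - (g * out).sum(axis=axis, keepdims=True))

        return Tensor(out, _parents=((self, grad_fn),))

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_grad_fn(i):
        def grad_fn(g):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(idx)]

        return grad_fn

    parents = tuple((t, make_grad_fn(i)) for i, t in enumerate(tensors))
    return Tensor(np.concatenate(datas, axis=axis), _parents=parents)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean multinomial cross-entropy from raw logits (stable log-softmax)."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = logits.shape[0]
    value = -logp[np.arange(n), labels].mean()
    probs = np.exp(logp)

    def grad_fn(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        return g * d / n

    return Tensor(np.asarray(value, dtype=logits.data.dtype), _parents=((logits, grad_fn),))


class Module:
    """Base for layers: tracks parameters, train/eval mode, recursively."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            for m in _collect_modules(value):
                mods.append(m)
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield value
        for sub in vars(value).values():
            yield from _collect_modules(sub)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect_modules(v)


class Adam:
    """Adam with optional decoupled-from-loss L2 penalty added to gradients."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * (g * g)
            mhat = self._m[i] / (1 - b1**self.t)
            vhat = self._v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
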