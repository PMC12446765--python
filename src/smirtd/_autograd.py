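"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to train a small transformer encoder on CPU: broadcasting
arithmetic, batched matmul, reshape/transpose, reductions, GELU, softmax (with an
additive constant bias for attention masking), embedding gather, layer norm, and
numerically fused cross-entropy / binary-cross-entropy losses.

Gradients accumulate into ``Tensor.grad`` on ``backward()``; the graph is a DAG
of ``Tensor`` nodes built eagerly.  No in-place mutation of ``data`` after a node
enters a graph.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "softmax", "cross_entropy", "bce_with_logits", "layer_norm", "gelu", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Sequence["Tensor"] = (),
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._prev = tuple(_prev)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ----- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        src = self.data.shape
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(src))
        return out

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod([self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - y**2))
        return out

    def take_rows(self, ids: np.ndarray) -> "Tensor":
        """Embedding gather: ``self`` is a (V, d) table, ids any integer shape."""
        out = Tensor(self.data[ids], _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            acc = np.zeros_like(self.data)
            np.add.at(acc, ids.reshape(-1), g.reshape(-1, self.data.shape[-1]))
            self._accum(acc)

        out._backward = bw
        return out

    # ----- backprop --------------------------------------------------------

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ----- composite ops --------------------------------------------------------


def softmax(x: Tensor, bias: Optional[np.ndarray] = None) -> Tensor:
    """Row softmax along the last axis, with an optional additive constant bias
    (used for padding masks: bias = -1e9 on masked keys)."""
    z = x.data if bias is None else x.data + bias
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=-1, keepdims=True)
            x._accum((g - dot) * y)

    out._backward = bw
    return out


def gelu(x: Tensor) -> Tensor:
    """Tanh-approximation GELU."""
    c = np.sqrt(2.0 / np.pi)
    inner = (c * (x.data + 0.044715 * x.data**3))
    t = np.tanh(inner)
    y = 0.5 * x.data * (1.0 + t)
    out = Tensor(y, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            dt = (1.0 - t**2) * c * (1.0 + 3 * 0.044715 * x.data**2)
            x._accum(g * (0.5 * (1.0 + t) + 0.5 * x.data * dt))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gain: Tensor, shift: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * _rsqrt(var, eps) * gain + shift


def _rsqrt(v: Tensor, eps: float) -> Tensor:
    y = 1.0 / np.sqrt(v.data + eps)
    out = Tensor(y, _prev=(v,))
    out._backward = lambda g: v.requires_grad and v._accum(-0.5 * g * y**3)
    return out


def dropout(x: Tensor, ratio: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when ratio == 0."""
    if ratio <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= ratio) / (1.0 - ratio)
    return x * Tensor(keep)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``logits`` (N, V), ``targets`` (N,) int ids."""
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    nll = logsumexp - z[np.arange(n), targets]
    out = Tensor(nll.mean(), _prev=(logits,))

    def bw(g):
        if logits.requires_grad:
            p = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
            p[np.arange(n), targets] -= 1.0
            logits._accum(g * p / n)

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over positions where ``mask`` is true."""
    m = mask.astype(float)
    n = max(m.sum(), 1.0)
    z = logits.data
    # log(1 + e^-|z|) + max(z, 0) - z*y, stable for large |z|
    loss = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * labels
    out = Tensor((loss * m).sum() / n, _prev=(logits,))

    def bw(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accum(g * (sig - labels) * m / n)

    out._backward = bw
    return out
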