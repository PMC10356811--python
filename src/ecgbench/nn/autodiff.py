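"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operation that produced
it; calling :meth:`Tensor.backward` on a scalar loss walks the graph in
reverse topological order and accumulates gradients.  Only the operations
needed by the 1-D architectures in this package are provided; convolution is
implemented by im2col over ``numpy.lib.stride_tricks.sliding_window_view``,
and the recurrent and attention layers are single graph nodes with
hand-written backward passes (see :mod:`ecgbench.nn.layers`), which keeps
graphs small even for long sequences.

All gradient implementations are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[], None]] = None,
    ):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- graph traversal ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _prev=(self,))
        inv = np.argsort(axes)

        def bwd():
            if self.requires_grad:
                self._accum(out.grad.transpose(*inv))

        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------

    def leaky_relu(self, alpha: float = 0.3):
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data), _prev=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, alpha))

        out._backward = bwd
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, _prev=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * y * (1.0 - y))

        out._backward = bwd
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - y * y))

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = bwd
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * y)

        out._backward = bwd
        return out

    def clip_min(self, lo: float):
        mask = self.data >= lo
        out = Tensor(np.maximum(self.data, lo), _prev=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out._backward = bwd
        return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def bwd():
        if a.requires_grad:
            a._accum(out.grad @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ out.grad)

    out._backward = bwd
    return out


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D cross-correlation with 'same' zero padding.

    x: (N, C, L); w: (F, C, K); b: (F,); output (N, F, L).
    """
    N, C, L = x.data.shape
    F, C2, K = w.data.shape
    assert C == C2, f"channel mismatch {C} vs {C2}"
    pl = (K - 1) // 2
    pr = K - 1 - pl
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    cols = sliding_window_view(xp, K, axis=2)  # (N, C, L, K)
    out_data = np.einsum("nclk,fck->nfl", cols, w.data, optimize=True)
    out_data += b.data[None, :, None]
    out = Tensor(out_data, _prev=(x, w, b))

    def bwd():
        g = out.grad  # (N, F, L)
        if w.requires_grad:
            w._accum(np.einsum("nclk,nfl->fck", cols, g, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (K - 1 - pl, pl)))
            gcols = sliding_window_view(gp, K, axis=2)  # (N, F, L, K)
            x._accum(
                np.einsum("nflk,fck->ncl", gcols, w.data[:, :, ::-1], optimize=True)
            )

    out._backward = bwd
    return out


def maxpool1d(x: Tensor, size: int = 2, stride: int = 2) -> Tensor:
    """Max pooling along the last axis; trailing remainder is dropped."""
    N, C, L = x.data.shape
    Lo = (L - size) // stride + 1
    if Lo < 1:
        raise ValueError(f"input length {L} too short for pooling")
    windows = sliding_window_view(x.data, size, axis=2)[:, :, ::stride]  # (N,C,Lo,size)
    arg = windows.argmax(axis=3)
    out = Tensor(windows.max(axis=3), _prev=(x,))

    def bwd():
        g = np.zeros_like(x.data)
        n_i, c_i, l_i = np.meshgrid(
            np.arange(N), np.arange(C), np.arange(Lo), indexing="ij"
        )
        np.add.at(g, (n_i, c_i, l_i * stride + arg), out.grad)
        x._accum(g)

    out._backward = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, L) -> (N, C) mean over time."""
    return x.mean(axis=2)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Repeat each time step ``factor`` times along the last axis."""
    out = Tensor(np.repeat(x.data, factor, axis=2), _prev=(x,))

    def bwd():
        if x.requires_grad:
            N, C, L = x.data.shape
            x._accum(out.grad.reshape(N, C, L, factor).sum(axis=3))

    out._backward = bwd
    return out


def fit_len(x: Tensor, target: int) -> Tensor:
    """Crop or zero-pad the last axis to exactly ``target`` samples."""
    N, C, L = x.data.shape
    if L == target:
        return x
    if L > target:
        out = Tensor(x.data[:, :, :target], _prev=(x,))

        def bwd():
            if x.requires_grad:
                g = np.zeros_like(x.data)
                g[:, :, :target] = out.grad
                x._accum(g)

    else:
        out = Tensor(
            np.pad(x.data, ((0, 0), (0, 0), (0, target - L))), _prev=(x,)
        )

        def bwd():
            if x.requires_grad:
                x._accum(out.grad[:, :, :L])

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _prev=(x,))

    def bwd():
        if x.requires_grad:
            g = out.grad
            x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over the batch, fused with softmax for stability."""
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(loss, _prev=(logits,))

    def bwd():
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * p / n)

    out._backward = bwd
    return out
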