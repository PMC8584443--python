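"""Minimal reverse-mode automatic differentiation over numpy arrays.

No deep-learning framework ships with the target environment, so the capsule
network is built on this small tensor engine: a :class:`Tensor` records the
operations producing it and :meth:`Tensor.backward` accumulates gradients by
reverse topological traversal. Only the operations the model needs are
implemented (broadcast arithmetic, batched matmul, 2D convolution via
im2col, pooling reductions, sigmoid/ReLU/softmax, embedding lookup).

All tensors are float32 by default; gradients match the data dtype.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concatenate", "conv2d", "embedding", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32 if not isinstance(
            data, np.ndarray) else data.dtype)
        if self.data.dtype == np.float64:
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or bool(_parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion depth
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bwd(g):
            self._accum(
                _unbroadcast(np.matmul(g, other.data.swapaxes(-1, -2)), self.shape)
            )
            other._accum(
                _unbroadcast(np.matmul(self.data.swapaxes(-1, -2), g), other.shape)
            )

        out._backward = bwd
        return out

    # -- reductions and reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient is split equally among tied maxima."""
        m = self.data.max(axis=axis, keepdims=True)
        out = Tensor(m if keepdims else m.squeeze(axis), _parents=(self,))

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == m).astype(self.data.dtype)
            mask /= mask.sum(axis=axis, keepdims=True)
            self._accum(mask * g)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(np.argsort(axes)))
        return out

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        from scipy.special import expit  # avoids overflow warnings at extreme logits

        y = expit(self.data).astype(self.data.dtype)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * y * (1 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _parents=(self,))

        def bwd(g):
            self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        out._backward = bwd
        return out


def concatenate(tensors: list[Tensor], axis: int) -> Tensor:
    parts = [t.data for t in tensors]
    out = Tensor(np.concatenate(parts, axis=axis), _parents=tuple(tensors))
    sizes = [p.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # N,C,Ho,Wo,kh,kw
    n, c, ho, wo = windows.shape[:4]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2D cross-correlation of ``x`` (N,C,H,W) with ``weight`` (O,C,kh,kw)."""
    n, c, h, w = x.shape
    o, c2, kh, kw = weight.shape
    if c != c2:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {c2}")
    if h + 2 * pad < kh or w + 2 * pad < kw:
        raise ValueError(
            f"conv2d: spatial input {h}x{w} (pad {pad}) smaller than kernel {kh}x{kw}"
        )
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(o, -1)
    out_data = (cols @ wmat.T + bias.data).transpose(0, 2, 1).reshape(n, o, ho, wo)
    out = Tensor(out_data, _parents=(x, weight, bias))

    def bwd(g):
        gmat = g.reshape(n, o, ho * wo).transpose(0, 2, 1)  # N,L,O
        weight._accum(
            np.einsum("nlo,nlk->ok", gmat, cols).reshape(weight.shape)
        )
        bias._accum(g.sum(axis=(0, 2, 3)))
        dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
        dxp = np.zeros(
            (n, c, h + 2 * pad, w + 2 * pad), dtype=x.data.dtype
        )
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        x._accum(dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp)

    out._backward = bwd
    return out


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``table[indices]`` with scatter-add gradient to the table."""
    idx = np.asarray(indices)
    if idx.min() < 0 or idx.max() >= table.shape[0]:
        raise IndexError(
            f"embedding index out of range [0, {table.shape[0]}): "
            f"[{idx.min()}, {idx.max()}]"
        )
    out = Tensor(table.data[idx], _parents=(table,))

    def bwd(g):
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, idx, g)

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer (beta1 0.9, beta2 0.999) over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
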