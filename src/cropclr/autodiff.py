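"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine: every operation on :class:`Tensor` records its
parents and a backward closure; :meth:`Tensor.backward` runs a topological
sweep accumulating gradients. Only the operations the model zoo needs are
provided (elementwise arithmetic with broadcasting, matmul, 2-D convolution
and max-pooling, reductions, shape ops, softmax-style nonlinearities).

All data is float64. Gradients are plain numpy arrays on ``Tensor.grad``.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        data = self.data ** p

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        return Tensor._make(data, (self,), bw)

    # -- matmul ---------------------------------------------------------------
    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires both operands to be at least 2-D")
        data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(data, (self, other), bw)

    # -- nonlinearities -------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        data = self.data * mask

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(data, (self,), bw)

    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * data)

        return Tensor._make(data, (self,), bw)

    def log(self) -> "Tensor":
        data = np.log(self.data)

        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(data, (self,), bw)

    def sigmoid(self) -> "Tensor":
        data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * data * (1.0 - data))

        return Tensor._make(data, (self,), bw)

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - data * data))

        return Tensor._make(data, (self,), bw)

    def softplus(self) -> "Tensor":
        # numerically stable log(1+exp(x)); used for positivity transforms
        data = np.logaddexp(0.0, self.data)

        def bw(g):
            self._accumulate(g / (1.0 + np.exp(-self.data)))

        return Tensor._make(data, (self,), bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(data, (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy()
                                 if np.ndim(g) else np.full(self.shape, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)

        def bw(g):
            self._accumulate(g.reshape(self.shape))

        return Tensor._make(data, (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(data, (self,), bw)

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(data, (self,), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(data, tensors, bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    out = (x - m).exp().sum(axis=axis, keepdims=True).log() + m
    if not keepdims:
        out = out.reshape(tuple(s for i, s in enumerate(out.shape)
                                if i != (axis % x.ndim)))
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (F, C, kh, kw)."""
    n, c, h, wd = x.shape
    f, cw, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, weight {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (wd + 2 * padding - kw) // stride + 1
    out = np.zeros((n, f, oh, ow))
    for u in range(kh):
        for v in range(kw):
            patch = xp[:, :, u:u + stride * oh:stride, v:v + stride * ow:stride]
            out += np.einsum("ncij,fc->nfij", patch, w.data[:, :, u, v])
    if b is not None:
        out += b.data[None, :, None, None]

    parents = [x, w] + ([b] if b is not None else [])

    def bw(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for u in range(kh):
                for v in range(kw):
                    patch = xp[:, :, u:u + stride * oh:stride, v:v + stride * ow:stride]
                    gw[:, :, u, v] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    gxp[:, :, u:u + stride * oh:stride, v:v + stride * ow:stride] += \
                        np.einsum("nfij,fc->ncij", g, w.data[:, :, u, v])
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    fill = -np.inf
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=fill)
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    windows = np.empty((n, c, oh, ow, kernel * kernel))
    k = 0
    for u in range(kernel):
        for v in range(kernel):
            windows[..., k] = xp[:, :, u:u + stride * oh:stride, v:v + stride * ow:stride]
            k += 1
    arg = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gxp = np.zeros_like(xp)
        k = 0
        for u in range(kernel):
            for v in range(kernel):
                gxp[:, :, u:u + stride * oh:stride, v:v + stride * ow:stride] += \
                    g * (arg == k)
                k += 1
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    return Tensor._make(out, (x,), bw)
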