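"""Neural-network layers and optimizers on top of :mod:`cropclr.autodiff`.

Layers are plain Python objects holding :class:`~cropclr.autodiff.Tensor`
parameters; ``named_parameters`` walks attributes in insertion order, so the
parameter ordering (and hence serialization) is deterministic. Initialization
always draws from an explicit ``numpy.random.Generator``.

Normalization layers are group/layer norm (no running statistics), so the
forward pass is identical in training and inference and independent of batch
composition.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat, conv2d, max_pool2d, no_grad, softmax


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Minimal module base: parameter discovery, state dicts, train/eval."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Tensor) and attr.requires_grad:
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(f"{full}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def checksum(self) -> float:
        """Order-stable scalar fingerprint of all parameters (freeze checks)."""
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class GroupNorm(Module):
    def __init__(self, n_groups: int, n_channels: int, eps: float = 1e-5):
        if n_channels % n_groups:
            raise ValueError("channels must divide into groups")
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.n_groups = n_groups
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.n_groups
        xg = x.reshape(n, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2.0).mean(axis=2, keepdims=True)
        xn = (xg - mu) * (var + self.eps) ** -0.5
        xn = xn.reshape(n, c, h, w)
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product attention, softmax(QKᵀ/√d_k)V, with head masking.

    Queries may come from a different (shorter) sequence than keys/values,
    which is how class tokens attend over patch tokens. ``head_mask`` zeroes
    the output contribution of pruned heads.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"embedding dim {dim} not divisible by {n_heads} heads")
        self.wq = Linear(dim, dim, rng, bias=False)
        self.wk = Linear(dim, dim, rng, bias=False)
        self.wv = Linear(dim, dim, rng, bias=False)
        self.wo = Linear(dim, dim, rng, bias=False)
        self.n_heads = n_heads
        self.d_k = dim // n_heads
        self.head_mask: np.ndarray | None = None  # (n_heads,) of {0,1}

    def _split(self, x: Tensor) -> Tensor:
        b, s, c = x.shape
        return x.reshape(b, s, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, query: Tensor, key_value: Tensor | None = None
                ) -> tuple[Tensor, Tensor]:
        """Returns (output (B,Sq,C), attention weights (B,heads,Sq,Skv))."""
        kv = query if key_value is None else key_value
        q = self._split(self.wq(query))
        k = self._split(self.wk(kv))
        v = self._split(self.wv(kv))
        logits = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(self.d_k))
        attn = softmax(logits, axis=-1)
        out = attn @ v
        if self.head_mask is not None:
            out = out * Tensor(self.head_mask.reshape(1, -1, 1, 1))
        b, nh, sq, dk = out.shape
        out = out.transpose(0, 2, 1, 3).reshape(b, sq, nh * dk)
        return self.wo(out), attn


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerLayer(Module):
    """Post-norm transformer block: LN(x + MHA(x)), LN(x + FFN(x))."""

    def __init__(self, dim: int, n_heads: int, ffn_hidden: int,
                 rng: np.random.Generator):
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_hidden, rng)
        self.norm2 = LayerNorm(dim)

    def forward(self, x: Tensor, key_value: Tensor | None = None
                ) -> tuple[Tensor, Tensor]:
        a, attn = self.attn(x, key_value)
        x = self.norm1(x + a)
        x = self.norm2(x + self.ffn(x))
        return x, attn


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class SGD:
    """Momentum SGD with (decoupled-style, applied-to-grad) weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: list[Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


__all__ = [
    "Adam", "Conv2d", "FeedForward", "GroupNorm", "LayerNorm", "Linear",
    "Module", "MultiHeadAttention", "Parameter", "SGD", "Tensor",
    "TransformerLayer", "concat", "conv2d", "max_pool2d", "no_grad", "softmax",
]
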