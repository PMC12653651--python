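"""Viewpoint-invariant contrastive encoding.

A primary encoder (residual backbone → affine adapter → two-layer projection
head, 512→128→128 with an interleaved ReLU) produces unit-norm embeddings
z_i of one augmented view; a momentum encoder — an architecture-identical
copy updated only by exponential moving average θ′ ← m·θ′ + (1−m)·θ,
m = 0.999 — embeds the other view and feeds a FIFO queue of negatives.
The InfoNCE loss with temperature τ = 0.2 pulls the positive pair together
against all queued negatives:

    L = −log  exp(sim(z_i, z_j)/τ) / (exp(sim(z_i, z_j)/τ) + Σ_k exp(sim(z_i, z_k⁻)/τ))

Gradient never flows through the momentum branch or the queue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .backbones import ResidualBackbone, bilinear_resize_grid, build_backbone
from .nn import Conv2d, Linear, Module
from .synthetic import ImageSample


@dataclass
class ContrastiveConfig:
    tau: float = 0.2               # InfoNCE temperature
    momentum: float = 0.999        # EMA coefficient m
    queue_capacity: int = 4096     # K
    embed_dim: int = 128           # d
    proj_in: int = 512
    proj_hidden: int = 128
    backbone_profile: str = "paper"
    tiny_width: int = 16
    input_size: int = 512
    grid_channels: int = 128       # C of the spatial feature grid
    grid_size: int = 16            # H = W of the spatial feature grid

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if self.queue_capacity < 1:
            raise ValueError("queue capacity must be ≥ 1")


def images_to_tensor(samples: list[ImageSample]) -> Tensor:
    """Stack uint8 images into a (B, 3, H, W) tensor scaled to [−1, 1]."""
    arr = np.stack([s.pixels for s in samples]).astype(np.float64)
    arr = arr.transpose(0, 3, 1, 2) / 127.5 - 1.0
    return Tensor(arr)


class Encoder(Module):
    """Backbone f_θ, projection head g_θ, and the spatial-grid adapter.

    ``forward`` returns the unit-norm embedding z = g(f(x)) together with the
    spatial feature grid consumed by the diffusion filter and the fine-tuning
    head. The grid is a hypercolumn: every backbone stage's output (stem
    included) is bilinearly resized to ``grid_size²``, channel-concatenated,
    and 1×1-projected to ``grid_channels`` — mid-level stages carry the
    texture statistics that the deepest, most instance-specific stage loses.
    """

    def __init__(self, config: ContrastiveConfig, rng: np.random.Generator):
        self.backbone: ResidualBackbone = build_backbone(
            config.backbone_profile, rng, tiny_width=config.tiny_width)
        feat = self.backbone.feature_dim
        self.adapter = (Linear(feat, config.proj_in, rng)
                        if feat != config.proj_in else None)
        self.proj1 = Linear(config.proj_in, config.proj_hidden, rng)
        self.proj2 = Linear(config.proj_hidden, config.embed_dim, rng)
        # first- and second-order hypercolumn channels: attention heads can
        # only take weighted means over patches, so texture (dispersion)
        # statistics must be present as explicit channels
        self.grid_adapter = Conv2d(2 * self.backbone.hypercolumn_dim,
                                   config.grid_channels, 1, rng)
        self.config = config

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        pooled, stages = self.backbone.forward_stages(x)
        h = pooled if self.adapter is None else self.adapter(pooled)
        z = self.proj2(self.proj1(h).relu())
        z = z * ((z ** 2.0).sum(axis=-1, keepdims=True) + 1e-24) ** -0.5
        g = self.config.grid_size
        column = concat([bilinear_resize_grid(s, g, g) for s in stages],
                        axis=1)
        column = concat([column, column * column], axis=1)
        grid = self.grid_adapter(column)
        return z, grid


def encode_project(samples: list[ImageSample] | ImageSample,
                   encoder: Encoder) -> np.ndarray:
    """Inference-mode unit-norm embeddings for one or more images."""
    single = isinstance(samples, ImageSample)
    batch = [samples] if single else samples
    with no_grad():
        z, _ = encoder(images_to_tensor(batch))
    out = z.numpy()
    return out[0] if single else out


def ema_update(momentum_encoder: Module, encoder: Module, m: float) -> None:
    """θ′ ← m·θ′ + (1−m)·θ, elementwise over congruent parameter sets."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("momentum must lie in [0, 1]")
    prim = dict(encoder.named_parameters())
    for name, p_m in momentum_encoder.named_parameters():
        if name not in prim:
            raise KeyError(f"momentum parameter {name!r} missing from primary")
        p = prim[name]
        if p.data.shape != p_m.data.shape:
            raise ValueError(f"shape mismatch for {name}")
        p_m.data *= m
        p_m.data += (1.0 - m) * p.data


def make_momentum_encoder(encoder: Encoder,
                          rng: np.random.Generator) -> Encoder:
    """Architecture-identical copy initialized to the primary's parameters."""
    clone = Encoder(encoder.config, rng)
    clone.load_state_dict(encoder.state_dict())
    return clone


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


class NegativeQueue:
    """FIFO buffer of unit-norm momentum embeddings, capacity K."""

    def __init__(self, capacity: int, dim: int):
        if capacity < 1:
            raise ValueError("capacity must be ≥ 1")
        self.capacity = capacity
        self.dim = dim
        self._buf: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self._buf)

    def push(self, batch: np.ndarray) -> None:
        batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
        norms = np.linalg.norm(batch, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-5):
            raise ValueError("queue entries must be unit-norm")
        for row in batch:
            self._buf.append(row.copy())
        if len(self._buf) > self.capacity:
            self._buf = self._buf[len(self._buf) - self.capacity:]

    def as_array(self) -> np.ndarray:
        if not self._buf:
            return np.zeros((0, self.dim))
        return np.stack(self._buf)

    def state(self) -> np.ndarray:
        return self.as_array()

    @classmethod
    def from_state(cls, arr: np.ndarray, capacity: int) -> "NegativeQueue":
        q = cls(capacity, arr.shape[1])
        if len(arr):
            q.push(arr)
        return q


def info_nce_loss(z_i, z_j, queue: NegativeQueue | np.ndarray,
                  tau: float) -> Tensor:
    """InfoNCE over one embedding pair or a batch (mean-reduced).

    ``z_i`` may be a Tensor on the tape (primary branch); ``z_j`` and the
    queue are treated as constants.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    negatives = queue.as_array() if isinstance(queue, NegativeQueue) else \
        np.atleast_2d(np.asarray(queue, dtype=np.float64))
    if negatives.shape[0] == 0:
        raise ValueError("negative queue is empty")
    zi = z_i if isinstance(z_i, Tensor) else Tensor(np.asarray(z_i))
    if zi.ndim == 1:
        zi = zi.reshape(1, -1)
    zj = np.atleast_2d(np.asarray(z_j.numpy() if isinstance(z_j, Tensor)
                                  else z_j, dtype=np.float64))
    s_pos = (zi * Tensor(zj)).sum(axis=-1, keepdims=True)        # (B, 1)
    s_neg = zi @ Tensor(negatives.T)                             # (B, K)
    logits = concat([s_pos, s_neg], axis=1) * (1.0 / tau)
    # −log softmax at index 0, numerically stable via logsumexp
    m = Tensor(logits.numpy().max(axis=1, keepdims=True))
    lse = ((logits - m).exp().sum(axis=1, keepdims=True)).log() + m
    loss = lse - logits[:, 0:1]
    return loss.mean()


@dataclass
class ContrastiveStepOutput:
    loss: Tensor                   # InfoNCE (primary branch on the tape)
    per_pair_loss: Tensor          # (B, 1) before mean reduction
    z_i: Tensor                    # (B, d) primary embeddings
    z_j: np.ndarray                # (B, d) momentum embeddings (constant)
    grid_i: Tensor                 # (B, C, H, W) primary feature grids
    grid_j: np.ndarray             # (B, C, H, W) momentum feature grids


def contrastive_step(pairs, encoder: Encoder, momentum_encoder: Encoder,
                     queue: NegativeQueue, config: ContrastiveConfig,
                     pair_mask: np.ndarray | None = None,
                     update: bool = True) -> ContrastiveStepOutput:
    """One contrastive forward over a batch of view pairs.

    z_i comes from the primary encoder on x_i (gradient flows); z_j from the
    momentum encoder on x_j (no gradient). The loss is computed against the
    queue *before* pushing, the momentum encoder is EMA-updated, and z_j is
    enqueued afterwards. ``pair_mask`` (0/1 per pair) excludes filtered pairs
    from the loss while their momentum embeddings are still queued.
    """
    from .augment import ViewPair  # local import avoids a cycle at import time
    if isinstance(pairs, ViewPair):
        pairs = [pairs]
    x_i = images_to_tensor([p.x_i for p in pairs])
    x_j = images_to_tensor([p.x_j for p in pairs])
    z_i, grid_i = encoder(x_i)
    with no_grad():
        z_j_t, grid_j_t = momentum_encoder(x_j)
    z_j = z_j_t.numpy()
    grid_j = grid_j_t.numpy()

    negatives = queue.as_array()
    if negatives.shape[0] == 0:
        raise ValueError("negative queue is empty; warm it up before stepping")
    s_pos = (z_i * Tensor(z_j)).sum(axis=-1, keepdims=True)
    s_neg = z_i @ Tensor(negatives.T)
    logits = concat([s_pos, s_neg], axis=1) * (1.0 / config.tau)
    m = Tensor(logits.numpy().max(axis=1, keepdims=True))
    lse = ((logits - m).exp().sum(axis=1, keepdims=True)).log() + m
    per_pair = lse - logits[:, 0:1]                              # (B, 1)
    if pair_mask is not None:
        kept = float(pair_mask.sum())
        weights = Tensor(pair_mask.reshape(-1, 1).astype(np.float64))
        loss = (per_pair * weights).sum() * (1.0 / max(kept, 1.0))
    else:
        loss = per_pair.mean()

    if update:
        ema_update(momentum_encoder, encoder, config.momentum)
        # re-normalize against drift before queueing
        z_j_push = z_j / np.linalg.norm(z_j, axis=1, keepdims=True)
        queue.push(z_j_push)
    return ContrastiveStepOutput(loss, per_pair, z_i, z_j, grid_i, grid_j)


__all__ = ["ContrastiveConfig", "ContrastiveStepOutput", "Encoder",
           "NegativeQueue", "contrastive_step", "cosine_similarity",
           "ema_update", "encode_project", "images_to_tensor",
           "info_nce_loss", "make_momentum_encoder"]
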