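"""Few-shot fine-tuning by class-token attention aggregation.

The pretrained backbone is frozen; its spatial feature grid F (H×W×C) is
flattened to patch tokens, and N learnable class tokens attend over the
patches through a 3-layer, 8-head attention stack with FFN widths
128→256→128, layer normalization and residual connections:

    Attention(Q, K, V) = softmax(QKᵀ/√d_k)·V,   Q = W_Q·T_c, K = W_K·P, V = W_V·P

Only the class/register tokens are updated by attention (the patch tokens
are a constant dictionary), which is what makes the head cheap. The N class
token outputs are concatenated into a single linear classification head with
sigmoid outputs, trained with multi-label binary cross-entropy on one-hot
targets; evaluation decodes the single label by argmax. Attention maps are
row-stochastic over patches and double as pseudo-masks; heads can be pruned
to the top-k by an attention-mass importance score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, no_grad, softmax
from .contrastive import Encoder, images_to_tensor
from .nn import (FeedForward, LayerNorm, Linear, Module, MultiHeadAttention,
                 Parameter, SGD)
from .synthetic import ImageSample


@dataclass
class FinetuneConfig:
    n_classes: int = 3             # N class tokens, matched to the label space
    dim: int = 128                 # C
    n_layers: int = 3
    n_heads: int = 8
    ffn_hidden: int = 256
    n_registers: int = 0
    lr: float = 1e-3               # momentum-SGD settings for the head
    momentum: float = 0.9
    weight_decay: float = 5e-4
    epochs: int = 200
    batch_size: int = 16
    val_fraction: float = 0.0      # >0 enables early stopping on a held-out fold
    patience: int = 20
    standardize_grids: bool = True # per-channel z-score fit on the k-shot set

    def __post_init__(self) -> None:
        if self.dim % self.n_heads:
            raise ValueError(f"dim {self.dim} not divisible by "
                             f"{self.n_heads} heads")


@dataclass
class LossWeights:
    lambda_diff: float = 0.5       # λ1
    lambda_cls: float = 1.0        # λ2

    def __post_init__(self) -> None:
        if self.lambda_diff < 0 or self.lambda_cls < 0:
            raise ValueError("loss weights must be nonnegative")


class CrossAttentionLayer(Module):
    """Class/register tokens attend over patch tokens; patches unchanged."""

    def __init__(self, dim: int, n_heads: int, ffn_hidden: int,
                 rng: np.random.Generator):
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_hidden, rng)
        self.norm2 = LayerNorm(dim)

    def forward(self, tokens: Tensor, patches: Tensor
                ) -> tuple[Tensor, Tensor]:
        a, attn = self.attn(tokens, patches)
        tokens = self.norm1(tokens + a)
        tokens = self.norm2(tokens + self.ffn(tokens))
        return tokens, attn


class AttentionHead(Module):
    """Class-token aggregation head over a frozen feature grid."""

    def __init__(self, config: FinetuneConfig, rng: np.random.Generator):
        c, n = config.dim, config.n_classes
        self.class_tokens = Parameter(rng.normal(0.0, 0.02, size=(n, c)))
        self.register_tokens = (Parameter(
            rng.normal(0.0, 0.02, size=(config.n_registers, c)))
            if config.n_registers else None)
        self.patch_proj = Linear(c, c, rng)
        self.layers = [CrossAttentionLayer(c, config.n_heads,
                                           config.ffn_hidden, rng)
                       for _ in range(config.n_layers)]
        self.classifier = Linear(n * c, n, rng)
        self.config = config
        # optional per-channel input standardization, fit on the k-shot set
        self.input_mean: np.ndarray | None = None
        self.input_std: np.ndarray | None = None

    def set_input_stats(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.input_mean = np.asarray(mean, dtype=np.float64)
        self.input_std = np.asarray(std, dtype=np.float64)

    def _standardize(self, grid: Tensor) -> Tensor:
        if self.input_mean is None:
            return grid
        c = self.config.dim
        return (grid - Tensor(self.input_mean.reshape(1, c, 1, 1))) * \
            Tensor(1.0 / self.input_std.reshape(1, c, 1, 1))

    def build_token_sequence(self, grid: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (query tokens (B, N+R, C), patch tokens (B, HW, C)).

        Patch token k corresponds to grid cell (k // W, k % W), row-major.
        """
        b, c, h, w = grid.shape
        if c != self.config.dim:
            raise ValueError(f"grid channel width {c} != head dim "
                             f"{self.config.dim}")
        grid = self._standardize(grid)
        patches = grid.reshape(b, c, h * w).transpose(0, 2, 1)
        patches = self.patch_proj(patches)
        ones = Tensor(np.ones((b, 1, 1)))
        toks = [ones * self.class_tokens]
        if self.register_tokens is not None:
            toks.append(ones * self.register_tokens)
        return concat(toks, axis=1) if len(toks) > 1 else toks[0], patches

    def forward(self, grid: Tensor) -> tuple[Tensor, list[np.ndarray]]:
        """ŷ ∈ (0,1)^N and per-layer head-averaged class→patch attention."""
        tokens, patches = self.build_token_sequence(grid)
        n = self.config.n_classes
        attn_maps: list[np.ndarray] = []
        for layer in self.layers:
            tokens, attn = layer(tokens, patches)
            # (B, heads, N+R, HW) → head-averaged class rows (B, N, HW)
            attn_maps.append(attn.numpy()[:, :, :n, :].mean(axis=1))
        b = tokens.shape[0]
        cls_out = tokens[:, :n, :].reshape(b, n * self.config.dim)
        yhat = self.classifier(cls_out).sigmoid()
        return yhat, attn_maps

    def raw_attention(self, grid: Tensor) -> list[np.ndarray]:
        """Per-layer per-head class→patch attention, (B, heads, N, HW)."""
        tokens, patches = self.build_token_sequence(grid)
        out = []
        for layer in self.layers:
            tokens, attn = layer(tokens, patches)
            out.append(attn.numpy()[:, :, :self.config.n_classes, :])
        return out


def class_token_attention(tokens: np.ndarray, patches: np.ndarray,
                          attn: MultiHeadAttention
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Single cross-attention application (N×C tokens over HW×C patches).

    Returns (outputs N×C, head-averaged attention N×HW). Exposed for direct
    inspection; the head's layers use the same primitive internally.
    """
    t = Tensor(np.asarray(tokens, dtype=np.float64)[None])
    p = Tensor(np.asarray(patches, dtype=np.float64)[None])
    with no_grad():
        out, a = attn(t, p)
    return out.numpy()[0], a.numpy()[0].mean(axis=0)


def multilabel_bce(y, yhat, eps: float = 1e-7):
    """−(1/N) Σ_i [y_i log ŷ_i + (1−y_i) log(1−ŷ_i)], batch-mean if batched."""
    yt = Tensor(np.asarray(y, dtype=np.float64)) if not isinstance(y, Tensor) else y
    ph = yhat if isinstance(yhat, Tensor) else Tensor(np.asarray(yhat, dtype=np.float64))
    if yt.shape != ph.shape:
        raise ValueError(f"shape mismatch: y {yt.shape} vs ŷ {ph.shape}")
    ph = ph.clip(eps, 1.0 - eps)
    ll = yt * ph.log() + (1.0 - yt) * (1.0 - ph).log()
    return -ll.mean()


def total_loss(l_contrast, l_diff, l_cls, weights: LossWeights):
    """L_total = L_contrast + λ1·L_diff + λ2·L_cls."""
    return l_contrast + weights.lambda_diff * l_diff + weights.lambda_cls * l_cls


def prune_heads(head_importance: np.ndarray, keep_count: int) -> np.ndarray:
    """0/1 mask keeping the ``keep_count`` highest-importance heads.

    Ties broken in favour of the lower head index (stable sort on −score).
    """
    scores = np.asarray(head_importance, dtype=np.float64)
    if not 1 <= keep_count <= len(scores):
        raise ValueError(f"keep_count must lie in [1, {len(scores)}]")
    order = np.argsort(-scores, kind="stable")
    mask = np.zeros(len(scores))
    mask[order[:keep_count]] = 1.0
    return mask


def head_importance(head: AttentionHead, grids: Tensor) -> np.ndarray:
    """Per-head importance over a calibration batch.

    Importance of a head = mean over samples and class tokens of its maximum
    attention mass on any patch (how sharply it localizes), averaged over
    layers.
    """
    with no_grad():
        per_layer = head.raw_attention(grids)
    scores = [a.max(axis=-1).mean(axis=(0, 2)) for a in per_layer]
    return np.mean(scores, axis=0)


def apply_head_mask(head: AttentionHead, mask: np.ndarray) -> None:
    for layer in head.layers:
        layer.attn.head_mask = None if mask is None else np.asarray(mask, float)


def attention_pseudo_mask(attn_row_map: np.ndarray, class_index: int,
                          quantile: float, grid_hw: tuple[int, int]
                          ) -> np.ndarray:
    """Binary H×W mask: patches at/above the class row's quantile threshold."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    row = np.asarray(attn_row_map, dtype=np.float64)[class_index]
    # "lower" keeps the q→0 limit exact (threshold = min ⇒ all-ones mask)
    thresh = np.quantile(row, quantile, method="lower")
    mask = (row >= thresh).astype(np.uint8)
    return mask.reshape(grid_hw)


# ---------------------------------------------------------------------------
# k-shot training
# ---------------------------------------------------------------------------

@dataclass
class FinetuneResult:
    head: AttentionHead
    loss_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    epochs_run: int = 0


def extract_grids(encoder: Encoder, samples: list[ImageSample],
                  batch_size: int = 32) -> np.ndarray:
    """Frozen-backbone feature grids for a list of images (no gradient)."""
    grids = []
    for i in range(0, len(samples), batch_size):
        with no_grad():
            _, g = encoder(images_to_tensor(samples[i:i + batch_size]))
        grids.append(g.numpy())
    return np.concatenate(grids, axis=0)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def finetune(encoder: Encoder, kshot_samples: list[ImageSample], k: int,
             config: FinetuneConfig, seed: int = 0) -> FinetuneResult:
    """Train the attention head on exactly k labelled images per class.

    The encoder is frozen: it is only ever run in inference mode and its
    parameters are not handed to the optimizer, so they are bit-identical
    before and after.
    """
    labels = np.array([s.label for s in kshot_samples])
    if any(l is None for l in labels):
        raise ValueError("k-shot samples must all be labelled")
    counts = np.bincount(labels, minlength=config.n_classes)
    if len(counts) != config.n_classes or np.any(counts != k):
        raise ValueError(f"protocol violation: expected exactly {k} samples "
                         f"per class, got counts {counts.tolist()}")

    rng = np.random.default_rng(seed)
    head = AttentionHead(config, rng)
    grids = extract_grids(encoder, kshot_samples)
    if config.standardize_grids:
        head.set_input_stats(grids.mean(axis=(0, 2, 3)),
                             grids.std(axis=(0, 2, 3)) + 1e-9)
    targets = _one_hot(labels, config.n_classes)

    n = len(kshot_samples)
    idx = rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    val_idx, train_idx = idx[:n_val], idx[n_val:]

    opt = SGD(head.parameters(), lr=config.lr, momentum=config.momentum,
              weight_decay=config.weight_decay)
    result = FinetuneResult(head=head)
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            yhat, _ = head(Tensor(grids[sel]))
            loss = multilabel_bce(targets[sel], yhat)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(sel)
        result.loss_history.append(epoch_loss / len(order))
        result.epochs_run = epoch + 1
        if n_val:
            with no_grad():
                yv, _ = head(Tensor(grids[val_idx]))
            vloss = multilabel_bce(targets[val_idx], yv).item()
            result.val_history.append(vloss)
            if vloss < best_val - 1e-6:
                best_val, best_state, stale = vloss, head.state_dict(), 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_state is not None:
        head.load_state_dict(best_state)
    return result


def predict(head: AttentionHead, grids: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """(argmax labels, sigmoid scores) for a stack of feature grids."""
    with no_grad():
        yhat, _ = head(Tensor(grids))
    scores = yhat.numpy()
    return scores.argmax(axis=1), scores


__all__ = ["AttentionHead", "CrossAttentionLayer", "FinetuneConfig",
           "FinetuneResult", "LossWeights", "apply_head_mask",
           "attention_pseudo_mask", "class_token_attention", "extract_grids",
           "finetune", "head_importance", "multilabel_bce", "predict",
           "prune_heads", "total_loss"]
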