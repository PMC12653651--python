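"""Diffusion-based filtering of contrastive view pairs.

Aggressive augmentation can destroy the semantics that make two views of an
image a valid positive pair ("semantic drift"). This module scores pair
consistency in feature space: the encoder's spatial feature grid e₀ is
progressively corrupted by Gaussian noise,

    q(e_t | e₀) = N(e_t ; α_t·e₀, (1 − α_t)·I),

a transformer-based conditional variational decoder with mean and scale
branches μ_θ(e_t, t), η_θ(e_t, t) learns to reverse the corruption under the
variational objective  L_diff = Σ_t ‖e_{t−1} − μ_θ(e_t, t)‖²,  and the two
views' reconstructed grids ẽ₁, ẽ₂ are compared by a covariance-structure
distance

    D_struct = 1 − Tr(Σ₁ Σ₂) / (‖Σ₁‖_F · ‖Σ₂‖_F).

Pairs whose distance falls below the retention threshold δ are kept as
positives; the rest are excluded from the contrastive loss of that step.
The joint pretraining objective is L_contrast + λ·L_diff with λ = 0.5.

Note the mean coefficient is α_t itself, not the √ᾱ_t of the standard
denoising-diffusion parameterization; ``schedule_convention`` switches to
the cumulative-product convention for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import Linear, Module, Parameter, TransformerLayer


@dataclass
class DiffusionSchedule:
    """Noise schedule α_1..α_T, each in (0, 1], monotone non-increasing."""

    alphas: np.ndarray

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=np.float64)
        if self.alphas.ndim != 1 or len(self.alphas) < 1:
            raise ValueError("schedule must be a non-empty 1-D sequence")
        if np.any(self.alphas <= 0) or np.any(self.alphas > 1):
            raise ValueError("every α_t must lie in (0, 1]")
        if np.any(np.diff(self.alphas) > 1e-12):
            raise ValueError("schedule must be monotone non-increasing")

    @property
    def T(self) -> int:
        return len(self.alphas)

    @classmethod
    def linear(cls, T: int = 10, alpha_start: float = 0.95,
               alpha_end: float = 0.5) -> "DiffusionSchedule":
        return cls(np.linspace(alpha_start, alpha_end, T))


@dataclass
class DiffusionConfig:
    T: int = 10
    alpha_start: float = 0.95
    alpha_end: float = 0.5
    schedule_convention: str = "as_printed"   # or "sqrt_cumulative"
    dim: int = 128                            # C of the feature grid
    grid_size: int = 16
    n_layers: int = 4
    n_heads: int = 8
    ffn_hidden: int = 512
    stop_gradient: bool = False               # block L_diff gradient into e₀

    def schedule(self) -> DiffusionSchedule:
        return DiffusionSchedule.linear(self.T, self.alpha_start, self.alpha_end)


def _mean_scale(schedule: DiffusionSchedule, t: int,
                convention: str) -> tuple[float, float]:
    if not 1 <= t <= schedule.T:
        raise ValueError(f"timestep {t} outside [1, {schedule.T}]")
    if convention == "as_printed":
        a = schedule.alphas[t - 1]
        return float(a), float(np.sqrt(1.0 - a))
    if convention == "sqrt_cumulative":
        abar = float(np.prod(schedule.alphas[:t]))
        return float(np.sqrt(abar)), float(np.sqrt(1.0 - abar))
    raise ValueError(f"unknown schedule convention {convention!r}")


def forward_diffuse(e_0: np.ndarray, schedule: DiffusionSchedule, t: int,
                    rng: np.random.Generator,
                    convention: str = "as_printed") -> np.ndarray:
    """Sample e_t ~ N(α_t·e₀, (1 − α_t)·I), elementwise, shape-preserving."""
    e_0 = np.asarray(e_0, dtype=np.float64)
    mean_c, std = _mean_scale(schedule, t, convention)
    return mean_c * e_0 + std * rng.standard_normal(e_0.shape)


def forward_trajectory(e_0, schedule: DiffusionSchedule,
                       rng: np.random.Generator,
                       convention: str = "as_printed") -> list:
    """[e₀, e₁, …, e_T]; e₀ may be a Tensor (keeps the encoder gradient)."""
    base = e_0.numpy() if isinstance(e_0, Tensor) else np.asarray(e_0)
    traj = [e_0]
    for t in range(1, schedule.T + 1):
        traj.append(forward_diffuse(base, schedule, t, rng, convention))
    return traj


class ReconstructionNet(Module):
    """Conditional variational decoder over feature-grid tokens.

    The H×W×C grid is flattened to H·W tokens of width C, given learned
    positional and (additive) timestep embeddings, passed through
    ``n_layers`` transformer blocks, and decoded by two tokenwise affine
    branches: the mean μ and a strictly positive scale η (softplus + ε).
    """

    def __init__(self, config: DiffusionConfig, rng: np.random.Generator):
        c, hw = config.dim, config.grid_size * config.grid_size
        self.pos_embed = Parameter(rng.normal(0.0, 0.02, size=(hw, c)))
        self.time_embed = Parameter(rng.normal(0.0, 0.02, size=(config.T + 1, c)))
        self.layers = [TransformerLayer(c, config.n_heads, config.ffn_hidden, rng)
                       for _ in range(config.n_layers)]
        self.mu_head = Linear(c, c, rng)
        self.eta_head = Linear(c, c, rng)
        self.config = config

    def forward(self, e_t: Tensor, t: int) -> tuple[Tensor, Tensor]:
        if not 1 <= t <= self.config.T:
            raise ValueError(f"timestep {t} outside [1, {self.config.T}]")
        b, c, h, w = e_t.shape
        if c != self.config.dim or h * w != self.pos_embed.shape[0]:
            raise ValueError(f"grid shape {(c, h, w)} does not match the net")
        x = e_t.reshape(b, c, h * w).transpose(0, 2, 1)        # (B, HW, C)
        x = x + self.pos_embed + self.time_embed[t].reshape(1, 1, c)
        for layer in self.layers:
            x, _ = layer(x)
        mu = self.mu_head(x).transpose(0, 2, 1).reshape(b, c, h, w)
        eta = (self.eta_head(x).softplus() + 1e-6
               ).transpose(0, 2, 1).reshape(b, c, h, w)
        return mu, eta


def reverse_step(e_t, t: int, net: ReconstructionNet
                 ) -> tuple[Tensor, Tensor]:
    x = e_t if isinstance(e_t, Tensor) else Tensor(np.asarray(e_t, dtype=np.float64))
    if x.ndim == 3:
        mu, eta = net(x.reshape(1, *x.shape), t)
        return mu.reshape(*x.shape), eta.reshape(*x.shape)
    return net(x, t)


def reconstruct(e_T, schedule: DiffusionSchedule,
                net: ReconstructionNet) -> Tensor:
    """Mean-path reverse iteration ẽ_{t−1} := μ_θ(ẽ_t, t), t = T … 1."""
    e = e_T if isinstance(e_T, Tensor) else Tensor(np.asarray(e_T, dtype=np.float64))
    for t in range(schedule.T, 0, -1):
        e, _ = reverse_step(e, t, net)
    return e


def diffusion_loss(trajectory: list, net: ReconstructionNet) -> Tensor:
    """Σ_{t=1..T} ‖e_{t−1} − μ_θ(e_t, t)‖² (batch-mean if batched)."""
    if len(trajectory) != net.config.T + 1:
        raise ValueError(f"trajectory length {len(trajectory)} does not match "
                         f"T={net.config.T}")
    total = None
    for t in range(1, len(trajectory)):
        target = trajectory[t - 1]
        if not isinstance(target, Tensor):
            target = Tensor(np.asarray(target, dtype=np.float64))
        e_t = trajectory[t]
        mu, _ = reverse_step(e_t, t, net)
        diff = target - mu
        if diff.ndim == 4:
            term = (diff ** 2.0).sum(axis=(1, 2, 3)).mean()
        else:
            term = (diff ** 2.0).sum()
        total = term if total is None else total + term
    return total


# ---------------------------------------------------------------------------
# Covariance structural distance and pair filtering
# ---------------------------------------------------------------------------

def feature_covariance(e: np.ndarray) -> np.ndarray:
    """Spatial covariance of a (C, H, W) feature grid.

    The H·W positions are the observations of a C-dimensional variable:
    Σ = (1/(H·W)) · X_centeredᵀ X_centered, a symmetric PSD C×C matrix.
    """
    if isinstance(e, Tensor):
        e = e.numpy()
    e = np.asarray(e, dtype=np.float64)
    if e.ndim != 3:
        raise ValueError(f"expected a (C, H, W) grid, got shape {e.shape}")
    c, h, w = e.shape
    if h * w < 2:
        raise ValueError("covariance undefined for a single spatial position")
    x = e.reshape(c, h * w).T                     # (HW, C) observations
    x = x - x.mean(axis=0, keepdims=True)
    cov = x.T @ x / (h * w)
    return 0.5 * (cov + cov.T)                    # enforce exact symmetry


def structural_distance(cov1: np.ndarray, cov2: np.ndarray) -> float:
    """D = 1 − Tr(Σ₁Σ₂)/(‖Σ₁‖_F·‖Σ₂‖_F); symmetric, in [0,1] for PSD inputs."""
    cov1 = np.asarray(cov1, dtype=np.float64)
    cov2 = np.asarray(cov2, dtype=np.float64)
    n1 = np.linalg.norm(cov1, "fro")
    n2 = np.linalg.norm(cov2, "fro")
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("structural distance undefined for a zero covariance")
    return float(1.0 - np.trace(cov1 @ cov2) / (n1 * n2))


def pair_structural_distance(e1: np.ndarray, e2: np.ndarray) -> float:
    return structural_distance(feature_covariance(e1), feature_covariance(e2))


@dataclass
class FilterConfig:
    delta: float = 0.5               # fixed retention threshold on D_struct
    delta_mode: str = "batch-quantile"
    delta_quantile: float = 0.8      # retain ≈ this fraction per batch
    lam: float = 0.5                 # joint-loss weight λ

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("δ must be nonnegative")
        if self.lam < 0:
            raise ValueError("λ must be nonnegative")
        if not 0.0 < self.delta_quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        if self.delta_mode not in ("fixed", "batch-quantile"):
            raise ValueError("delta_mode must be 'fixed' or 'batch-quantile'")


def filter_pair(e1: np.ndarray, e2: np.ndarray,
                config: FilterConfig) -> tuple[bool, float]:
    """Keep the pair iff D_struct(ẽ₁, ẽ₂) < δ (fixed-threshold decision)."""
    d = pair_structural_distance(e1, e2)
    return bool(d < config.delta), d


def filter_batch(distances: np.ndarray, config: FilterConfig) -> np.ndarray:
    """0/1 keep mask for a batch of pair distances."""
    distances = np.asarray(distances, dtype=np.float64)
    if config.delta_mode == "fixed":
        thresh = config.delta
    else:
        thresh = float(np.quantile(distances, config.delta_quantile))
    return (distances < thresh).astype(np.float64)


def joint_pretrain_loss(l_contrast, l_diff, lam: float):
    """L_joint = L_contrast + λ·L_diff (works on tensors or floats)."""
    return l_contrast + lam * l_diff


__all__ = ["DiffusionConfig", "DiffusionSchedule", "FilterConfig",
           "ReconstructionNet", "diffusion_loss", "feature_covariance",
           "filter_batch", "filter_pair", "forward_diffuse",
           "forward_trajectory", "joint_pretrain_loss",
           "pair_structural_distance", "reconstruct", "reverse_step",
           "structural_distance"]
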