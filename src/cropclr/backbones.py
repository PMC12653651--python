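"""Residual convolutional backbones.

Two profiles are provided:

``paper``
    A ResNet-50-style network — 7×7/2 stem, 3×3/2 max-pool, four bottleneck
    stages of depths (3, 4, 6, 3) with output widths (256, 512, 1024, 2048).
    With 512×512 inputs the last stage is a 16×16 spatial grid.

``tiny``
    A four-block residual convnet for desk-scale runs: the same topology at a
    fraction of the width/depth, so CPU training stays cheap.

Both expose ``forward`` returning the globally pooled feature vector together
with the last spatial feature grid (the diffusion filter consumes the grid).
Normalization is group norm, so outputs do not depend on batch composition.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import Conv2d, GroupNorm, Module, max_pool2d


def _n_groups(channels: int) -> int:
    for g in (8, 4, 2, 1):
        if channels % g == 0:
            return g
    return 1


class ConvNorm(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1):
        self.conv = Conv2d(c_in, c_out, kernel, rng, stride=stride,
                           padding=kernel // 2, bias=False)
        self.norm = GroupNorm(_n_groups(c_out), c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x))


class BasicBlock(Module):
    """Two 3×3 convolutions with identity (or projected) skip."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1):
        self.a = ConvNorm(c_in, c_out, 3, rng, stride=stride)
        self.b = ConvNorm(c_out, c_out, 3, rng)
        self.skip = (ConvNorm(c_in, c_out, 1, rng, stride=stride)
                     if (stride != 1 or c_in != c_out) else None)

    def forward(self, x: Tensor) -> Tensor:
        h = self.b(self.a(x).relu())
        s = x if self.skip is None else self.skip(x)
        return (h + s).relu()


class BottleneckBlock(Module):
    """1×1 reduce → 3×3 → 1×1 expand, the ResNet-50 building block."""

    def __init__(self, c_in: int, c_mid: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1):
        self.a = ConvNorm(c_in, c_mid, 1, rng)
        self.b = ConvNorm(c_mid, c_mid, 3, rng, stride=stride)
        self.c = ConvNorm(c_mid, c_out, 1, rng)
        self.skip = (ConvNorm(c_in, c_out, 1, rng, stride=stride)
                     if (stride != 1 or c_in != c_out) else None)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c(self.b(self.a(x).relu()).relu())
        s = x if self.skip is None else self.skip(x)
        return (h + s).relu()


class ResidualBackbone(Module):
    def __init__(self, rng: np.random.Generator, stem_width: int,
                 stage_widths: list[int], stage_depths: list[int],
                 bottleneck: bool, stem_kernel: int = 3, stem_pool: bool = False):
        self.stem = ConvNorm(3, stem_width, stem_kernel, rng, stride=2)
        self.stem_pool = stem_pool
        self.stages: list[Module] = []
        self.block_widths = [stem_width]
        c = stem_width
        for i, (w, d) in enumerate(zip(stage_widths, stage_depths)):
            first_stride = 1 if (i == 0 and stem_pool) else 2
            for j in range(d):
                stride = first_stride if j == 0 else 1
                if bottleneck:
                    self.stages.append(BottleneckBlock(c, w // 4, w, rng, stride))
                else:
                    self.stages.append(BasicBlock(c, w, rng, stride))
                self.block_widths.append(w)
                c = w
        self.feature_dim = c

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (pooled (B, feature_dim), spatial grid (B, C, H', W'))."""
        h = self.stem(x).relu()
        if self.stem_pool:
            h = max_pool2d(h, 3, 2, padding=1)
        for block in self.stages:
            h = block(h)
        pooled = h.mean(axis=(2, 3))
        return pooled, h

    def forward_stages(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Pooled final feature plus every stage's spatial output (stem first)."""
        h = self.stem(x).relu()
        if self.stem_pool:
            h = max_pool2d(h, 3, 2, padding=1)
        outputs = [h]
        for block in self.stages:
            h = block(h)
            outputs.append(h)
        return h.mean(axis=(2, 3)), outputs

    @property
    def hypercolumn_dim(self) -> int:
        return sum(self.block_widths)


def build_backbone(profile: str, rng: np.random.Generator,
                   tiny_width: int = 16) -> ResidualBackbone:
    if profile == "paper":
        return ResidualBackbone(rng, stem_width=64,
                                stage_widths=[256, 512, 1024, 2048],
                                stage_depths=[3, 4, 6, 3], bottleneck=True,
                                stem_kernel=7, stem_pool=True)
    if profile == "tiny":
        w = tiny_width
        return ResidualBackbone(rng, stem_width=w,
                                stage_widths=[w, 2 * w, 4 * w],
                                stage_depths=[1, 1, 1], bottleneck=False)
    raise ValueError(f"unknown backbone profile: {profile!r}")


def bilinear_resize_grid(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable bilinear resize of a (B, C, H, W) grid.

    Implemented as two fixed interpolation matrices applied by matmul, so the
    gradient flows through the autodiff engine with no special casing.
    """
    b, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x

    def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
        m = np.zeros((n_out, n_in))
        if n_in == 1:
            m[:, 0] = 1.0
            return m
        # half-pixel-centre mapping, clamped at the borders
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0.0, n_in - 1.0)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        m[np.arange(n_out), lo] += 1.0 - frac
        m[np.arange(n_out), hi] += frac
        return m

    rows = Tensor(interp_matrix(h, out_h))          # (out_h, h)
    cols = Tensor(interp_matrix(w, out_w).T)        # (w, out_w)
    y = x.reshape(b * c, h, w)
    y = rows @ y          # broadcasts to (B*C, out_h, w)
    y = y @ cols          # (B*C, out_h, out_w)
    return y.reshape(b, c, out_h, out_w)


__all__ = ["BasicBlock", "BottleneckBlock", "ResidualBackbone",
           "bilinear_resize_grid", "build_backbone"]
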