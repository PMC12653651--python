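"""Procedural generation of synthetic pest imagery.

Real field imagery of wheat pest damage is rarely shareable, so the package
ships a parametric generator: each class is a texture motif (spots, stripes,
blotches, rings — caricatures of feeding marks, rust-like pustules, chlorotic
patches and ring lesions) drawn over a leaf-like green background, with
nuisance variation in illumination, blur and viewpoint. Everything is a pure
function of ``(class_id, spec, seed)``, so fixtures are reproducible and need
no shipped binary data.

The generator's job is to give downstream training something learnable with
class structure comparable across runs, not to look like a photograph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

MOTIF_KINDS = ("spots", "stripes", "blotches", "rings")


@dataclass
class ImageSample:
    """An RGB raster with an optional class label."""

    pixels: np.ndarray            # (H, W, 3) uint8
    label: int | None
    source_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H×W×3, got {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError(f"image too small: {px.shape[:2]} (min 32×32)")
        if not np.isfinite(px.astype(np.float64)).all():
            raise ValueError("pixels must be finite")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class MotifParams:
    kind: str = "spots"
    density: float = 20.0          # expected number of motif elements
    scale: float = 0.06            # element size as a fraction of image side

    def __post_init__(self) -> None:
        if self.kind not in MOTIF_KINDS:
            raise ValueError(f"unknown motif kind {self.kind!r}; "
                             f"choose from {MOTIF_KINDS}")


def default_motifs(n_classes: int) -> list[MotifParams]:
    """One visually distinct motif per class, cycling through the kinds."""
    base = [
        MotifParams("spots", density=25.0, scale=0.045),
        MotifParams("stripes", density=7.0, scale=0.02),
        MotifParams("blotches", density=4.0, scale=0.16),
        MotifParams("rings", density=8.0, scale=0.10),
    ]
    out = []
    for c in range(n_classes):
        proto = base[c % len(base)]
        # later cycles shift density so repeated kinds stay separable
        boost = 1.0 + 0.8 * (c // len(base))
        out.append(MotifParams(proto.kind, proto.density * boost, proto.scale))
    return out


@dataclass
class SyntheticDatasetSpec:
    """Conditions under which a synthetic dataset is generated."""

    n_classes: int = 3
    per_class_count: int = 100
    image_size: int = 64
    motif_params: list[MotifParams] = field(default_factory=list)
    brightness_range: tuple[float, float] = (0.8, 1.2)
    blur_sigma_range: tuple[float, float] = (0.0, 1.0)
    rotation_max_deg: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be ≥ 2")
        if self.per_class_count < 1:
            raise ValueError("per_class_count must be ≥ 1")
        if self.image_size < 32:
            raise ValueError("image_size must be ≥ 32")
        if not self.motif_params:
            self.motif_params = default_motifs(self.n_classes)
        if len(self.motif_params) != self.n_classes:
            raise ValueError("motif_params must have one entry per class")


def _leaf_background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Green leaf-like base: smooth luminance field plus faint veins."""
    coarse = rng.normal(0.0, 1.0, size=(8, 8))
    fieldv = ndimage.zoom(coarse, size / 8.0, order=3)[:size, :size]
    fieldv = (fieldv - fieldv.min()) / (np.ptp(fieldv) + 1e-9)
    base = np.empty((size, size, 3))
    base[..., 0] = 55 + 35 * fieldv
    base[..., 1] = 120 + 60 * fieldv
    base[..., 2] = 45 + 30 * fieldv
    # diagonal vein striping at low contrast
    yy, xx = np.mgrid[0:size, 0:size]
    phase = rng.uniform(0, 2 * np.pi)
    veins = 6.0 * np.sin(2 * np.pi * (xx + 0.4 * yy) / (size / 6.0) + phase)
    return base + veins[..., None]


_MOTIF_COLOR = np.array([120.0, 78.0, 30.0])     # necrotic brown


def _draw_motif(img: np.ndarray, motif: MotifParams,
                rng: np.random.Generator) -> None:
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size))
    r = max(1.5, motif.scale * size)
    n = max(1, int(round(rng.normal(motif.density, 0.15 * motif.density))))
    if motif.kind == "spots":
        for _ in range(n):
            cy, cx = rng.uniform(0, size, size=2)
            rr = r * rng.uniform(0.7, 1.3)
            mask = np.maximum(mask, ((yy - cy) ** 2 + (xx - cx) ** 2) < rr ** 2)
    elif motif.kind == "stripes":
        theta = np.deg2rad(rng.uniform(30, 60))      # oblique streaks
        proj = xx * np.cos(theta) + yy * np.sin(theta)
        spacing = size / max(2.0, float(n))
        width = max(1.0, motif.scale * size)
        offset = rng.uniform(0, spacing)
        mask = ((proj + offset) % spacing) < width
    elif motif.kind == "blotches":
        noise = rng.normal(size=(size, size))
        smooth = ndimage.gaussian_filter(noise, sigma=r)
        thresh = np.quantile(smooth, 1.0 - min(0.45, 0.04 * n))
        mask = smooth > thresh
    elif motif.kind == "rings":
        for _ in range(n):
            cy, cx = rng.uniform(0.1 * size, 0.9 * size, size=2)
            rr = r * rng.uniform(0.7, 1.3)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            ring = (d2 < rr ** 2) & (d2 > (0.55 * rr) ** 2)
            mask = np.maximum(mask, ring)
    mask = mask.astype(float)
    jitter = rng.normal(1.0, 0.08, size=3)
    img[:] = img * (1 - mask[..., None]) + \
        (_MOTIF_COLOR * jitter)[None, None, :] * mask[..., None]


def generate_synthetic_image(class_id: int, spec: SyntheticDatasetSpec,
                             seed: int) -> ImageSample:
    """Render one image of class ``class_id``; pure in (class_id, spec, seed)."""
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} out of range "
                         f"[0, {spec.n_classes})")
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([spec.seed, class_id, seed])))
    img = _leaf_background(spec.image_size, rng)
    _draw_motif(img, spec.motif_params[class_id], rng)
    # nuisance: viewpoint (rotation), illumination, blur — class-independent
    angle = rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg)
    img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                         mode="reflect", order=1)
    img = img * rng.uniform(*spec.brightness_range)
    sigma = rng.uniform(*spec.blur_sigma_range)
    if sigma > 1e-3:
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0.0))
    img = np.clip(img, 0, 255).astype(np.uint8)
    return ImageSample(pixels=img, label=class_id,
                       source_id=f"c{class_id}_{seed:05d}")


__all__ = ["ImageSample", "MOTIF_KINDS", "MotifParams", "SyntheticDatasetSpec",
           "default_motifs", "generate_synthetic_image"]
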