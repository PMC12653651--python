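"""Preprocessing and multi-scale viewpoint augmentation.

The preprocessing path standardizes size (center-crop to square, bilinear
resize to ``target_size``) and normalizes color: histogram equalization of
the luminance (Y of YCbCr) channel and gray-world white balance. The
augmentation path draws, independently per view, a rotation
θ ~ U(−30°, 30°), a horizontal flip with probability 0.5, a scale factor
s ~ U(0.8, 1.2), a 3×3 Gaussian blur with σ ~ U(0.5, 1.5), and one or more
rectangular cutouts whose areas are uniform on [0.05·A, 0.2·A] of the image
area A. Two such draws applied to the same source image form a positive
view pair for contrastive training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import exposure

from .synthetic import ImageSample


@dataclass
class AugmentationParams:
    target_size: int = 512
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    flip_prob: float = 0.5
    scale_range: tuple[float, float] = (0.8, 1.2)
    blur_kernel: int = 3
    sigma_range: tuple[float, float] = (0.5, 1.5)
    cutout_fraction_range: tuple[float, float] = (0.05, 0.20)
    cutout_fill: str = "gray"              # or "zero"
    n_cutouts_range: tuple[int, int] = (1, 3)
    color_normalize: bool = True

    def __post_init__(self) -> None:
        for name in ("rotation_range", "scale_range", "sigma_range",
                     "cutout_fraction_range", "n_cutouts_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low ≤ high")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be a probability")
        if self.target_size < 32:
            raise ValueError("target_size must be ≥ 32")
        if self.cutout_fill not in ("gray", "zero"):
            raise ValueError("cutout_fill must be 'gray' or 'zero'")


#: Realized per-view draw; kept on the pair for reproducibility audits.
@dataclass
class DrawnParams:
    theta: float = 0.0
    flip: bool = False
    scale: float = 1.0
    sigma: float = 0.0
    cutouts: list[tuple[int, int, int, int]] = field(default_factory=list)


@dataclass
class ViewPair:
    x_i: ImageSample
    x_j: ImageSample
    source_id: str
    drawn_params_i: DrawnParams
    drawn_params_j: DrawnParams


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def center_crop_box(h: int, w: int) -> tuple[int, int, int, int]:
    """(y0, y1, x0, x1) of the centered square crop to the shorter side."""
    side = min(h, w)
    y0 = (h - side) // 2
    x0 = (w - side) // 2
    return y0, y0 + side, x0, x0 + side


def _resize_bilinear(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    if (h, w) == (size, size):
        return img.astype(np.float64)
    zoom = (size / h, size / w, 1.0)
    return ndimage.zoom(img.astype(np.float64), zoom, order=1,
                        mode="nearest", grid_mode=True)


def standardize_image(img: ImageSample, target_size: int = 512) -> ImageSample:
    """Square-crop and bilinear-resize to ``target_size``.

    Aspect ratios above 2 would lose most of the long dimension to the crop,
    so those images are zero-padded to square instead.
    """
    px = img.pixels
    h, w = px.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    aspect = max(h, w) / min(h, w)
    if aspect > 2.0:
        side = max(h, w)
        canvas = np.zeros((side, side, 3), dtype=px.dtype)
        y0 = (side - h) // 2
        x0 = (side - w) // 2
        canvas[y0:y0 + h, x0:x0 + w] = px
        square = canvas
    else:
        y0, y1, x0, x1 = center_crop_box(h, w)
        square = px[y0:y1, x0:x1]
    out = _resize_bilinear(square, target_size)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return ImageSample(out, img.label, img.source_id)


def equalize_luminance(img: ImageSample) -> ImageSample:
    """Histogram-equalize Y of the YCbCr decomposition; chroma untouched."""
    ycbcr = skcolor.rgb2ycbcr(img.pixels)
    y = ycbcr[..., 0]
    # skimage's Y lives on [16, 235]; equalize on the unit interval then map back
    y_eq = exposure.equalize_hist(y) * (235.0 - 16.0) + 16.0
    ycbcr[..., 0] = y_eq
    rgb = skcolor.ycbcr2rgb(ycbcr) * 255.0
    out = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return ImageSample(out, img.label, img.source_id)


def gray_world_gains(img: ImageSample) -> np.ndarray:
    means = img.pixels.reshape(-1, 3).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("gray-world balance undefined for a zero-mean channel")
    return means.mean() / means


def gray_world_balance(img: ImageSample) -> ImageSample:
    """Scale channels so their (pre-clip) means equal the global mean."""
    gains = gray_world_gains(img)
    balanced = img.pixels.astype(np.float64) * gains[None, None, :]
    out = np.clip(np.rint(balanced), 0, 255).astype(np.uint8)
    return ImageSample(out, img.label, img.source_id)


def preprocess(img: ImageSample, params: AugmentationParams) -> ImageSample:
    out = standardize_image(img, params.target_size)
    if params.color_normalize:
        out = equalize_luminance(out)
        out = gray_world_balance(out)
    return out


# ---------------------------------------------------------------------------
# Stochastic augmentation
# ---------------------------------------------------------------------------

def sample_spatial_params(params: AugmentationParams,
                          rng: np.random.Generator
                          ) -> tuple[float, bool, float]:
    theta = rng.uniform(*params.rotation_range)
    flip = bool(rng.random() < params.flip_prob)
    s = rng.uniform(*params.scale_range)
    return theta, flip, s


def gaussian_kernel3(sigma: float) -> np.ndarray:
    """Normalized 3×3 Gaussian kernel with standard deviation ``sigma``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ax = np.array([-1.0, 0.0, 1.0])
    g1 = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g1, g1)
    return k / k.sum()


def apply_gaussian_blur(img: ImageSample, sigma: float) -> ImageSample:
    k = gaussian_kernel3(sigma)
    px = img.pixels.astype(np.float64)
    out = np.empty_like(px)
    for c in range(3):
        out[..., c] = ndimage.convolve(px[..., c], k, mode="reflect")
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return ImageSample(out, img.label, img.source_id)


def _sample_cutout_rect(h: int, w: int, frac_range: tuple[float, float],
                        rng: np.random.Generator) -> tuple[int, int, int, int]:
    area = h * w
    s = rng.uniform(frac_range[0] * area, frac_range[1] * area)
    ar = rng.uniform(0.5, 2.0)
    rh = int(np.clip(round(np.sqrt(s * ar)), 1, h))
    # choose width so the integer rectangle's area stays inside the band
    w_lo = int(np.ceil(frac_range[0] * area / rh))
    w_hi = int(min(w, np.floor(frac_range[1] * area / rh)))
    if w_lo > w_hi:       # rounding squeezed the band shut; fall back on height
        rh = int(np.clip(round(np.sqrt(frac_range[1] * area * 0.75)), 1, h))
        w_lo = int(np.ceil(frac_range[0] * area / rh))
        w_hi = int(min(w, np.floor(frac_range[1] * area / rh)))
    rw = int(np.clip(round(s / rh), w_lo, w_hi))
    y0 = int(rng.integers(0, h - rh + 1))
    x0 = int(rng.integers(0, w - rw + 1))
    return y0, x0, rh, rw


def apply_cutout(img: ImageSample, params: AugmentationParams,
                 rng: np.random.Generator
                 ) -> tuple[ImageSample, list[tuple[int, int, int, int]]]:
    """Insert rectangular occlusions; returns the image and (y0,x0,h,w) rects."""
    lo, hi = params.n_cutouts_range
    n = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    px = img.pixels.copy()
    fill = 128 if params.cutout_fill == "gray" else 0
    rects = []
    h, w = px.shape[:2]
    for _ in range(n):
        y0, x0, rh, rw = _sample_cutout_rect(
            h, w, params.cutout_fraction_range, rng)
        px[y0:y0 + rh, x0:x0 + rw] = fill
        rects.append((y0, x0, rh, rw))
    return ImageSample(px, img.label, img.source_id), rects


def _rotate(px: np.ndarray, theta: float) -> np.ndarray:
    if theta == 0.0:
        return px
    return ndimage.rotate(px, theta, axes=(0, 1), reshape=False,
                          mode="reflect", order=1)


def _rescale_keep_size(px: np.ndarray, s: float) -> np.ndarray:
    if s == 1.0:
        return px
    h, w = px.shape[:2]
    scaled = ndimage.zoom(px, (s, s, 1.0), order=1, mode="nearest")
    sh, sw = scaled.shape[:2]
    if s > 1.0:            # zoom in: center crop back to (h, w)
        y0 = (sh - h) // 2
        x0 = (sw - w) // 2
        return scaled[y0:y0 + h, x0:x0 + w]
    pad_y = h - sh
    pad_x = w - sw
    return np.pad(scaled,
                  ((pad_y // 2, pad_y - pad_y // 2),
                   (pad_x // 2, pad_x - pad_x // 2), (0, 0)),
                  mode="reflect")


def augment_view(img: ImageSample, params: AugmentationParams,
                 rng: np.random.Generator) -> tuple[ImageSample, DrawnParams]:
    """One stochastic draw of the full augmentation pipeline (post-preprocess)."""
    theta, flip, s = sample_spatial_params(params, rng)
    sigma = rng.uniform(*params.sigma_range)
    px = img.pixels.astype(np.float64)
    px = _rotate(px, theta)
    if flip:
        px = px[:, ::-1]
    px = _rescale_keep_size(px, s)
    out = ImageSample(np.clip(np.rint(px), 0, 255).astype(np.uint8),
                      img.label, img.source_id)
    if sigma > 0.0:
        out = apply_gaussian_blur(out, sigma)
    out, rects = apply_cutout(out, params, rng)
    return out, DrawnParams(theta, flip, s, sigma, rects)


def make_view_pair(x: ImageSample, params: AugmentationParams,
                   rng: np.random.Generator) -> ViewPair:
    base = preprocess(x, params)
    x_i, draw_i = augment_view(base, params, rng)
    x_j, draw_j = augment_view(base, params, rng)
    return ViewPair(x_i, x_j, x.source_id, draw_i, draw_j)


def disabled_params(target_size: int = 512) -> AugmentationParams:
    """All perturbations off: the pipeline reduces to standardization."""
    return AugmentationParams(
        target_size=target_size, rotation_range=(0.0, 0.0), flip_prob=0.0,
        scale_range=(1.0, 1.0), sigma_range=(0.0, 0.0),
        n_cutouts_range=(0, 0), color_normalize=False)


__all__ = ["AugmentationParams", "DrawnParams", "ViewPair", "apply_cutout",
           "apply_gaussian_blur", "augment_view", "center_crop_box",
           "disabled_params", "equalize_luminance", "gaussian_kernel3",
           "gray_world_balance", "gray_world_gains", "make_view_pair",
           "preprocess", "sample_spatial_params", "standardize_image"]
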