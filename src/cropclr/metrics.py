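"""Classification, detection-style and segmentation-style metrics, plus the
prediction-consistency robustness protocol.

Precision, recall and accuracy follow the usual confusion-count definitions;
mean average precision integrates the monotone-envelope precision–recall
curve; mIoU averages per-class TP/(TP+FP+FN). Robustness is measured as the
fraction of samples whose argmax prediction survives a perturbation
(rotations up to 50°, occlusion, brightness shifts) together with the mean
absolute change of the top predicted probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .synthetic import ImageSample


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def precision_recall_accuracy(c: ConfusionCounts
                              ) -> tuple[float, float, float]:
    """(precision, recall, accuracy); an undefined ratio is returned as nan."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    total = c.tp + c.tn + c.fp + c.fn
    accuracy = (c.tp + c.tn) / total if total else float("nan")
    return precision, recall, accuracy


def miou(per_class: Sequence[tuple[int, int, int]]) -> float:
    """Mean over classes of TP/(TP+FP+FN); empty classes are excluded."""
    ious = []
    for i, (tp, fp, fn) in enumerate(per_class):
        denom = tp + fp + fn
        if denom == 0:
            warnings.warn(f"class {i} has no pixels in either mask; excluded "
                          "from mIoU", stacklevel=2)
            continue
        ious.append(tp / denom)
    if not ious:
        raise ValueError("mIoU undefined: every class is empty")
    return float(np.mean(ious))


def average_precision(points: Sequence[tuple[float, float]]) -> float:
    """Area under the PR curve, all-point interpolation, monotone envelope.

    ``points`` are (precision, recall) pairs ordered by decreasing score
    threshold (recall non-decreasing).
    """
    if not len(points):
        raise ValueError("empty precision–recall point list")
    p = np.array([pt[0] for pt in points], dtype=np.float64)
    r = np.array([pt[1] for pt in points], dtype=np.float64)
    if np.any((p < 0) | (p > 1) | (r < 0) | (r > 1)):
        raise ValueError("precision/recall must lie in [0, 1]")
    # monotone non-increasing precision envelope from the right
    env = np.maximum.accumulate(p[::-1])[::-1]
    r_prev = np.concatenate([[0.0], r[:-1]])
    return float(np.sum((r - r_prev) * env))


def mean_ap(aps: Sequence[float]) -> float:
    if not len(aps):
        raise ValueError("no per-class AP values")
    return float(np.mean(aps))


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> np.ndarray:
    m = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(y_true, int), np.asarray(y_pred, int)):
        if not (0 <= t < n_classes and 0 <= p < n_classes):
            raise ValueError(f"label outside [0, {n_classes}): true={t} pred={p}")
        m[t, p] += 1
    return m


def per_class_counts(matrix: np.ndarray) -> list[tuple[int, int, int]]:
    """(TP_i, FP_i, FN_i) per class from a confusion matrix (rows = truth)."""
    out = []
    for i in range(matrix.shape[0]):
        tp = int(matrix[i, i])
        fp = int(matrix[:, i].sum() - tp)
        fn = int(matrix[i, :].sum() - tp)
        out.append((tp, fp, fn))
    return out


def macro_metrics(matrix: np.ndarray) -> dict[str, float]:
    """Macro precision/recall and overall accuracy from a confusion matrix."""
    n = matrix.sum()
    precs, recs = [], []
    for tp, fp, fn in per_class_counts(matrix):
        precs.append(tp / (tp + fp) if tp + fp else float("nan"))
        recs.append(tp / (tp + fn) if tp + fn else float("nan"))
    return {
        "accuracy": float(np.trace(matrix) / n) if n else float("nan"),
        "macro_precision": float(np.nanmean(precs)),
        "macro_recall": float(np.nanmean(recs)),
    }


def bce_dice_loss(pred: np.ndarray, target: np.ndarray,
                  smooth: float = 1.0, eps: float = 1e-7) -> float:
    """Mean pixelwise BCE plus (1 − smoothed Dice coefficient)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, eps, 1.0 - eps)
    bce = float(-(target * np.log(p) + (1 - target) * np.log(1 - p)).mean())
    inter = float((pred * target).sum())
    dice = (2.0 * inter + smooth) / (pred.sum() + target.sum() + smooth)
    return bce + (1.0 - float(dice))


# ---------------------------------------------------------------------------
# Robustness: prediction consistency under viewpoint perturbation
# ---------------------------------------------------------------------------

Perturbation = tuple[str, Callable[[ImageSample], ImageSample]]


def _rotate_sample(s: ImageSample, angle: float) -> ImageSample:
    px = ndimage.rotate(s.pixels.astype(np.float64), angle, axes=(0, 1),
                        reshape=False, mode="reflect", order=1)
    return ImageSample(np.clip(np.rint(px), 0, 255).astype(np.uint8),
                       s.label, s.source_id)


def _occlude_sample(s: ImageSample, fraction: float = 0.1) -> ImageSample:
    h, w = s.pixels.shape[:2]
    side = int(round(np.sqrt(fraction * h * w)))
    y0, x0 = (h - side) // 2, (w - side) // 2
    px = s.pixels.copy()
    px[y0:y0 + side, x0:x0 + side] = 128
    return ImageSample(px, s.label, s.source_id)


def _brightness_sample(s: ImageSample, factor: float) -> ImageSample:
    px = np.clip(np.rint(s.pixels.astype(np.float64) * factor), 0, 255)
    return ImageSample(px.astype(np.uint8), s.label, s.source_id)


def default_perturbations() -> list[Perturbation]:
    suite: list[Perturbation] = [
        (f"rotate_{a}", lambda s, a=a: _rotate_sample(s, a))
        for a in (10, 20, 30, 40, 50)
    ]
    suite.append(("occlusion_0.1", _occlude_sample))
    suite.append(("brightness_1.2", lambda s: _brightness_sample(s, 1.2)))
    suite.append(("brightness_0.8", lambda s: _brightness_sample(s, 0.8)))
    return suite


@dataclass
class RobustnessReport:
    consistency: float
    confidence_variation: float
    per_perturbation: dict[str, float] = field(default_factory=dict)
    suite: list[str] = field(default_factory=list)
    composite: float | None = None     # consistency·(1−variation); non-canonical

    def __post_init__(self) -> None:
        if not 0.0 <= self.consistency <= 1.0:
            raise ValueError("consistency must lie in [0, 1]")
        if not 0.0 <= self.confidence_variation <= 1.0:
            raise ValueError("confidence variation must lie in [0, 1]")


def prediction_consistency(predict_fn: Callable[[list[ImageSample]],
                                                tuple[np.ndarray, np.ndarray]],
                           samples: list[ImageSample],
                           perturbations: list[Perturbation] | None = None,
                           include_composite: bool = False
                           ) -> RobustnessReport:
    """Fraction of argmax-stable predictions and mean top-probability shift.

    ``predict_fn`` maps images to (argmax labels, per-class score rows).
    """
    if not samples:
        raise ValueError("empty sample set")
    if perturbations is None:
        perturbations = default_perturbations()
    base_labels, base_scores = predict_fn(samples)
    base_conf = np.asarray(base_scores).max(axis=1)
    per = {}
    stable, var = [], []
    for name, fn in perturbations:
        pert = [fn(s) for s in samples]
        labels, scores = predict_fn(pert)
        conf = np.asarray(scores).max(axis=1)
        same = (np.asarray(labels) == np.asarray(base_labels))
        per[name] = float(same.mean())
        stable.append(same)
        var.append(np.abs(conf - base_conf))
    consistency = float(np.concatenate(stable).mean())
    variation = float(np.concatenate(var).mean())
    return RobustnessReport(
        consistency=consistency, confidence_variation=variation,
        per_perturbation=per, suite=[n for n, _ in perturbations],
        composite=(consistency * (1.0 - variation)
                   if include_composite else None))


__all__ = ["ConfusionCounts", "RobustnessReport", "average_precision",
           "bce_dice_loss", "confusion_matrix", "default_perturbations",
           "macro_metrics", "mean_ap", "miou", "per_class_counts",
           "precision_recall_accuracy", "prediction_consistency"]
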