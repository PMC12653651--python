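"""Dataset manifests, image-folder I/O and stratified splitting.

A dataset on disk is a folder of PNG/JPEG images plus a CSV manifest with
columns ``path,source_id,label,split``. Paths are stored relative to the
manifest location. Splitting is stratified by label and keyed on
``source_id``: a source id lands in exactly one of train/val/test, which is
how leakage between subsets is prevented.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic import ImageSample, SyntheticDatasetSpec, generate_synthetic_image

SPLITS = ("train", "val", "test")


@dataclass
class ManifestRecord:
    path: str
    source_id: str
    label: int | None
    split: str = "train"

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)
    root: Path = Path(".")

    def __post_init__(self) -> None:
        ids = [r.source_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("source_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return DatasetManifest([r for r in self.records if r.split == split],
                               root=self.root)

    def labels(self) -> list[int | None]:
        return [r.label for r in self.records]

    def resolve(self, record: ManifestRecord) -> Path:
        return self.root / record.path

    def save(self, manifest_path: str | Path) -> Path:
        manifest_path = Path(manifest_path)
        with open(manifest_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["path", "source_id", "label", "split"])
            for r in self.records:
                w.writerow([r.path, r.source_id,
                            "" if r.label is None else r.label, r.split])
        return manifest_path

    @classmethod
    def load(cls, manifest_path: str | Path) -> "DatasetManifest":
        manifest_path = Path(manifest_path)
        records = []
        with open(manifest_path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(ManifestRecord(
                    path=row["path"], source_id=row["source_id"],
                    label=None if row["label"] == "" else int(row["label"]),
                    split=row["split"]))
        return cls(records, root=manifest_path.parent)


def write_image(sample: ImageSample, path: str | Path) -> None:
    Image.fromarray(sample.pixels, mode="RGB").save(path)


def read_image(path: str | Path, label: int | None,
               source_id: str) -> ImageSample:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    return ImageSample(pixels=pixels, label=label, source_id=source_id)


def generate_dataset(spec: SyntheticDatasetSpec,
                     out_dir: str | Path) -> DatasetManifest:
    """Render the full synthetic dataset to ``out_dir`` as PNGs + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for c in range(spec.n_classes):
        for i in range(spec.per_class_count):
            sample = generate_synthetic_image(c, spec, seed=i)
            rel = f"{sample.source_id}.png"
            write_image(sample, out_dir / rel)
            records.append(ManifestRecord(path=rel, source_id=sample.source_id,
                                          label=c))
    manifest = DatasetManifest(records, root=out_dir)
    manifest.save(out_dir / "manifest.csv")
    return manifest


def read_image_folder(manifest_path: str | Path
                      ) -> tuple[list[ImageSample], DatasetManifest]:
    manifest = DatasetManifest.load(manifest_path)
    samples = [read_image(manifest.resolve(r), r.label, r.source_id)
               for r in manifest.records]
    return samples, manifest


def write_image_folder(samples: list[ImageSample], out_dir: str | Path,
                       fmt: str = "png") -> DatasetManifest:
    if fmt not in ("png", "jpeg"):
        raise ValueError("fmt must be 'png' or 'jpeg'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for s in samples:
        rel = f"{s.source_id}.{ 'png' if fmt == 'png' else 'jpg' }"
        write_image(s, out_dir / rel)
        records.append(ManifestRecord(path=rel, source_id=s.source_id,
                                      label=s.label))
    manifest = DatasetManifest(records, root=out_dir)
    manifest.save(out_dir / "manifest.csv")
    return manifest


def _largest_remainder(n: int, ratios: tuple[float, float, float]) -> list[int]:
    quota = [r * n for r in ratios]
    counts = [int(np.floor(q)) for q in quota]
    frac = [q - c for q, c in zip(quota, counts)]
    for _ in range(n - sum(counts)):
        i = int(np.argmax(frac))
        counts[i] += 1
        frac[i] = -1.0
    return counts


def split_dataset(manifest: DatasetManifest,
                  ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> DatasetManifest:
    """Assign every source_id to exactly one of train/val/test.

    Stratified by label: each class is allotted its floor quota per split
    first; leftover items then fill whichever split is furthest below its
    global target, so global sizes match the ratios to within rounding.
    """
    if any(r < 0 for r in ratios) or not np.isclose(sum(ratios), 1.0, atol=1e-6):
        raise ValueError("ratios must be nonnegative and sum to 1")
    n = len(manifest)
    n_positive_splits = sum(r > 0 for r in ratios)
    if n < n_positive_splits:
        raise ValueError(f"{n} images cannot cover {n_positive_splits} splits")
    global_sizes = _largest_remainder(n, ratios)
    rng = np.random.default_rng(seed)

    by_label: dict[int | None, list[int]] = {}
    for idx, r in enumerate(manifest.records):
        by_label.setdefault(r.label, []).append(idx)

    assignment: dict[int, str] = {}
    assigned = [0, 0, 0]
    leftovers: list[int] = []
    for label in sorted(by_label, key=lambda v: (v is None, v)):
        idxs = np.array(by_label[label])
        rng.shuffle(idxs)
        pos = 0
        for s, ratio in enumerate(ratios):
            take = int(np.floor(ratio * len(idxs)))
            for idx in idxs[pos:pos + take]:
                assignment[int(idx)] = SPLITS[s]
            assigned[s] += take
            pos += take
        leftovers.extend(int(i) for i in idxs[pos:])
    rng.shuffle(leftovers)
    for idx in leftovers:
        deficits = [global_sizes[s] - assigned[s] for s in range(3)]
        s = int(np.argmax(deficits))
        assignment[idx] = SPLITS[s]
        assigned[s] += 1

    records = [ManifestRecord(r.path, r.source_id, r.label, assignment[i])
               for i, r in enumerate(manifest.records)]
    return DatasetManifest(records, root=manifest.root)


__all__ = ["DatasetManifest", "ManifestRecord", "SPLITS", "generate_dataset",
           "read_image", "read_image_folder", "split_dataset", "write_image",
           "write_image_folder"]
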