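"""Orchestration: joint pretraining, checkpointing, evaluation, robustness.

Pretraining couples the contrastive encoder with the diffusion filter: every
batch builds augmented view pairs, embeds them with the primary and momentum
encoders, scores pair consistency by the covariance structural distance of
the diffusion-reconstructed feature grids, and optimizes

    L_joint = L_contrast(kept pairs) + λ·L_diff

with Adam (lr 1e-4, batch 32 by default). Filtered-out pairs are excluded
from the InfoNCE term but their momentum embeddings still enter the negative
queue. Fine-tuning and evaluation then run on the frozen backbone.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .augment import AugmentationParams, make_view_pair, preprocess
from .autodiff import Tensor, no_grad
from .contrastive import (ContrastiveConfig, Encoder, NegativeQueue,
                          contrastive_step, make_momentum_encoder)
from .data import DatasetManifest, read_image
from .diffusion import (DiffusionConfig, FilterConfig, ReconstructionNet,
                        diffusion_loss, forward_trajectory,
                        pair_structural_distance, reconstruct)
from .finetune import (AttentionHead, FinetuneConfig, extract_grids, finetune,
                       predict)
from .metrics import (RobustnessReport, confusion_matrix, macro_metrics,
                      prediction_consistency)
from .nn import Adam
from .synthetic import ImageSample


@dataclass
class PretrainConfig:
    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 100

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr, batch size and epochs must be positive")


@dataclass
class RunConfig:
    """Bundle of every stage's configuration plus the master seed."""

    seed: int = 0
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    augment: AugmentationParams = field(default_factory=AugmentationParams)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    # color normalization is a robustness device of the pretraining path;
    # set True to also apply it to fine-tune/inference inputs
    inference_color_normalize: bool = False

    def __post_init__(self) -> None:
        # keep the stages dimensionally consistent
        self.augment.target_size = self.contrastive.input_size
        self.diffusion.dim = self.contrastive.grid_channels
        self.diffusion.grid_size = self.contrastive.grid_size
        self.finetune.dim = self.contrastive.grid_channels

    @classmethod
    def tiny(cls, seed: int = 0, n_classes: int = 3,
             input_size: int = 64) -> "RunConfig":
        """Desk-scale profile: small backbone, grid and transformer widths."""
        return cls(
            seed=seed,
            pretrain=PretrainConfig(epochs=10),
            contrastive=ContrastiveConfig(
                backbone_profile="tiny", tiny_width=16, input_size=input_size,
                proj_in=64, proj_hidden=64, embed_dim=32,
                grid_channels=64, grid_size=8, queue_capacity=1024),
            diffusion=DiffusionConfig(n_layers=2, n_heads=4, ffn_hidden=64),
            finetune=FinetuneConfig(n_classes=n_classes, n_layers=1,
                                    n_heads=4, ffn_hidden=64),
        )

    def inference_params(self) -> AugmentationParams:
        """Preprocessing used for fine-tune and evaluation inputs."""
        return dataclasses.replace(
            self.augment, color_normalize=self.inference_color_normalize)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in (sub or {}).items():
                if k not in fields:
                    raise KeyError(f"unknown {klass.__name__} option {k!r}")
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[k] = v
            return klass(**kwargs)

        return cls(
            seed=int(d.get("seed", 0)),
            inference_color_normalize=bool(
                d.get("inference_color_normalize", False)),
            pretrain=build(PretrainConfig, d.get("pretrain")),
            contrastive=build(ContrastiveConfig, d.get("contrastive")),
            diffusion=build(DiffusionConfig, d.get("diffusion")),
            filter=build(FilterConfig, d.get("filter")),
            augment=build(AugmentationParams, d.get("augment")),
            finetune=build(FinetuneConfig, d.get("finetune")),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PretrainState:
    encoder: Encoder
    momentum_encoder: Encoder
    diffusion_net: ReconstructionNet
    queue: NegativeQueue
    config: RunConfig
    step: int = 0
    history: dict[str, list[float]] = field(default_factory=lambda: {
        "joint_loss": [], "contrast_loss": [], "diffusion_loss": [],
        "retention": []})
    filter_log: list[tuple[int, str, float, int]] = field(default_factory=list)

    def save_filter_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step,pair_id,distance,kept\n")
            for step, pid, dist, kept in self.filter_log:
                fh.write(f"{step},{pid},{dist:.6f},{kept}\n")


def _load_split_samples(manifest: DatasetManifest,
                        split: str) -> list[ImageSample]:
    sub = manifest.subset(split)
    return [read_image(sub.resolve(r), r.label, r.source_id)
            for r in sub.records]


def pretrain(manifest: DatasetManifest, config: RunConfig,
             samples: list[ImageSample] | None = None,
             corrupt_fraction: float = 0.0) -> PretrainState:
    """Joint contrastive + diffusion pretraining on the train split.

    ``corrupt_fraction`` deliberately destroys that fraction of view pairs
    (one view replaced by a mostly-occluded image) — an injection hook used
    to study what the consistency filter buys.
    """
    if samples is None:
        samples = _load_split_samples(manifest, "train")
    if not samples:
        raise ValueError("train split is empty")

    ss = np.random.SeedSequence([config.seed, 101])
    rng_init, rng_aug, rng_order, rng_diff, rng_corrupt = [
        np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(5)]

    encoder = Encoder(config.contrastive, rng_init)
    momentum_encoder = make_momentum_encoder(encoder, rng_init)
    diff_net = ReconstructionNet(config.diffusion, rng_init)
    schedule = config.diffusion.schedule()
    queue = NegativeQueue(config.contrastive.queue_capacity,
                          config.contrastive.embed_dim)
    opt = Adam(encoder.parameters() + diff_net.parameters(),
               lr=config.pretrain.lr)
    state = PretrainState(encoder, momentum_encoder, diff_net, queue, config)

    # warm the queue with momentum embeddings of unaugmented images
    warm = samples[:config.pretrain.batch_size]
    from .contrastive import images_to_tensor
    with no_grad():
        z0, _ = momentum_encoder(images_to_tensor(
            [preprocess(s, config.augment) for s in warm]))
    z0 = z0.numpy()
    queue.push(z0 / np.linalg.norm(z0, axis=1, keepdims=True))

    n = len(samples)
    bs = config.pretrain.batch_size
    for epoch in range(config.pretrain.epochs):
        order = rng_order.permutation(n)
        ep = {"joint": 0.0, "con": 0.0, "dif": 0.0, "kept": 0.0, "tot": 0.0}
        for start in range(0, n, bs):
            batch = [samples[i] for i in order[start:start + bs]]
            pairs = [make_view_pair(s, config.augment, rng_aug) for s in batch]
            if corrupt_fraction > 0.0:
                pairs = [_corrupt_pair(p, rng_corrupt)
                         if rng_corrupt.random() < corrupt_fraction else p
                         for p in pairs]

            out = contrastive_step(pairs, encoder, momentum_encoder, queue,
                                   config.contrastive, update=False)
            # diffusion branch on the primary view's feature grid
            e0 = out.grid_i.detach() if config.diffusion.stop_gradient \
                else out.grid_i
            traj = forward_trajectory(e0, schedule, rng_diff,
                                      config.diffusion.schedule_convention)
            l_diff = diffusion_loss(traj, diff_net)

            # consistency filter on reconstructed grids of both views
            with no_grad():
                e_t_i = Tensor(traj[-1])
                rec_i = reconstruct(e_t_i, schedule, diff_net).numpy()
                grid_j = out.grid_j
                traj_j_T = forward_trajectory(
                    grid_j, schedule, rng_diff,
                    config.diffusion.schedule_convention)[-1]
                rec_j = reconstruct(Tensor(traj_j_T), schedule,
                                    diff_net).numpy()
            dists = np.array([pair_structural_distance(rec_i[b], rec_j[b])
                              for b in range(len(pairs))])
            from .diffusion import filter_batch
            mask = filter_batch(dists, config.filter)
            for b, p in enumerate(pairs):
                state.filter_log.append(
                    (state.step, p.source_id, float(dists[b]), int(mask[b])))

            # masked contrastive loss recomputed from the same embeddings
            kept = float(mask.sum())
            weights = Tensor(mask.reshape(-1, 1))
            l_con = (out.per_pair_loss * weights).sum() * (1.0 / max(kept, 1.0))
            l_joint = l_con + config.filter.lam * l_diff
            if not np.isfinite(l_joint.item()):
                raise FloatingPointError(
                    f"non-finite joint loss at step {state.step}: "
                    f"contrast={l_con.item()} diffusion={l_diff.item()}")
            opt.zero_grad()
            l_joint.backward()
            opt.step()

            from .contrastive import ema_update
            ema_update(momentum_encoder, encoder, config.contrastive.momentum)
            z_j = out.z_j / np.linalg.norm(out.z_j, axis=1, keepdims=True)
            queue.push(z_j)

            ep["joint"] += l_joint.item() * len(pairs)
            ep["con"] += l_con.item() * len(pairs)
            ep["dif"] += l_diff.item() * len(pairs)
            ep["kept"] += kept
            ep["tot"] += len(pairs)
            state.step += 1
        state.history["joint_loss"].append(ep["joint"] / ep["tot"])
        state.history["contrast_loss"].append(ep["con"] / ep["tot"])
        state.history["diffusion_loss"].append(ep["dif"] / ep["tot"])
        state.history["retention"].append(ep["kept"] / ep["tot"])
    return state


def _corrupt_pair(pair, rng: np.random.Generator):
    """Destroy one view's content: occlude ~60% of the image area."""
    from .augment import ViewPair
    px = pair.x_j.pixels.copy()
    h, w = px.shape[:2]
    rh, rw = int(0.78 * h), int(0.78 * w)      # 0.78² ≈ 0.61 of the area
    y0 = int(rng.integers(0, h - rh + 1))
    x0 = int(rng.integers(0, w - rw + 1))
    px[y0:y0 + rh, x0:x0 + rw] = 128
    x_j = ImageSample(px, pair.x_j.label, pair.x_j.source_id)
    return ViewPair(pair.x_i, x_j, pair.source_id,
                    pair.drawn_params_i, pair.drawn_params_j)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(state: PretrainState, path: str | Path,
                    head: AttentionHead | None = None) -> None:
    """Serialize the full pretraining state as one .npz bundle."""
    arrays: dict[str, np.ndarray] = {}
    for prefix, module in (("enc", state.encoder),
                           ("mom", state.momentum_encoder),
                           ("diff", state.diffusion_net)):
        for k, v in module.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    if head is not None:
        for k, v in head.state_dict().items():
            arrays[f"head/{k}"] = v
        if head.input_mean is not None:
            arrays["headstats/mean"] = head.input_mean
            arrays["headstats/std"] = head.input_std
    arrays["queue"] = state.queue.state()
    meta = {"version": __version__, "step": state.step,
            "config": state.config.to_dict(), "history": state.history,
            "has_head": head is not None}
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8).copy()
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path
                    ) -> tuple[PretrainState, AttentionHead | None]:
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    config = RunConfig.from_dict(meta["config"])
    rng = np.random.default_rng(0)      # overwritten by the saved state
    encoder = Encoder(config.contrastive, rng)
    momentum = Encoder(config.contrastive, rng)
    diff_net = ReconstructionNet(config.diffusion, rng)

    def sub(prefix):
        plen = len(prefix) + 1
        return {k[plen:]: v for k, v in arrays.items()
                if k.startswith(prefix + "/")}

    encoder.load_state_dict(sub("enc"))
    momentum.load_state_dict(sub("mom"))
    diff_net.load_state_dict(sub("diff"))
    queue_arr = arrays["queue"]
    queue = (NegativeQueue.from_state(queue_arr,
                                      config.contrastive.queue_capacity)
             if queue_arr.size else
             NegativeQueue(config.contrastive.queue_capacity,
                           config.contrastive.embed_dim))
    state = PretrainState(encoder, momentum, diff_net, queue, config,
                          step=int(meta["step"]), history=meta["history"])
    head = None
    if meta.get("has_head"):
        head = AttentionHead(config.finetune, rng)
        head.load_state_dict(sub("head"))
        if "headstats/mean" in arrays:
            head.set_input_stats(arrays["headstats/mean"],
                                 arrays["headstats/std"])
    return state, head


# ---------------------------------------------------------------------------
# Evaluation and the full experiment
# ---------------------------------------------------------------------------

def preprocess_samples(samples: list[ImageSample],
                       params: AugmentationParams) -> list[ImageSample]:
    return [preprocess(s, params) for s in samples]


def make_predict_fn(encoder: Encoder, head: AttentionHead,
                    params: AugmentationParams):
    """Closure mapping raw images to (argmax labels, score rows)."""

    def predict_fn(samples: list[ImageSample]):
        prepped = preprocess_samples(samples, params)
        grids = extract_grids(encoder, prepped)
        return predict(head, grids)

    return predict_fn


def evaluate(encoder: Encoder, head: AttentionHead,
             manifest: DatasetManifest, split: str,
             params: AugmentationParams) -> dict:
    """Confusion matrix plus macro precision/recall/accuracy on a split."""
    samples = _load_split_samples(manifest, split)
    if not samples:
        raise ValueError(f"split {split!r} is empty")
    n_classes = head.config.n_classes
    for s in samples:
        if s.label is None or not 0 <= s.label < n_classes:
            raise ValueError(f"sample {s.source_id} has label {s.label!r} "
                             f"outside [0, {n_classes})")
    pred_labels, _ = make_predict_fn(encoder, head, params)(samples)
    truth = np.array([s.label for s in samples])
    matrix = confusion_matrix(truth, pred_labels, n_classes)
    report = macro_metrics(matrix)
    report["n"] = len(samples)
    report["confusion_matrix"] = matrix
    return report


def select_kshot(manifest: DatasetManifest, k: int, n_classes: int,
                 seed: int, split: str = "train") -> list[ImageSample]:
    """Draw exactly k labelled images per class from a split."""
    sub = manifest.subset(split)
    rng = np.random.default_rng(seed)
    chosen = []
    for c in range(n_classes):
        recs = [r for r in sub.records if r.label == c]
        if len(recs) < k:
            raise ValueError(f"class {c} has only {len(recs)} train images, "
                             f"need {k}")
        for i in rng.choice(len(recs), size=k, replace=False):
            r = recs[int(i)]
            chosen.append(read_image(sub.resolve(r), r.label, r.source_id))
    return chosen


def run_experiment(manifest: DatasetManifest, config: RunConfig, k: int = 10,
                   corrupt_fraction: float = 0.0,
                   with_robustness: bool = False) -> dict:
    """Pretrain → k-shot fine-tune → test-split evaluation, one seed."""
    state = pretrain(manifest, config, corrupt_fraction=corrupt_fraction)
    infer_params = config.inference_params()
    kshot_raw = select_kshot(manifest, k, config.finetune.n_classes,
                             seed=config.seed)
    kshot = preprocess_samples(kshot_raw, infer_params)
    checksum_pre = state.encoder.checksum()
    ft = finetune(state.encoder, kshot, k, config.finetune, seed=config.seed)
    checksum_post = state.encoder.checksum()
    report = evaluate(state.encoder, ft.head, manifest, "test", infer_params)
    result = {
        "accuracy": report["accuracy"],
        "macro_precision": report["macro_precision"],
        "macro_recall": report["macro_recall"],
        "confusion_matrix": report["confusion_matrix"],
        "n_test": report["n"],
        "retention": state.history["retention"],
        "joint_loss": state.history["joint_loss"],
        "finetune_loss": ft.loss_history,
        "backbone_checksum_pre": checksum_pre,
        "backbone_checksum_post": checksum_post,
        "state": state,
        "head": ft.head,
    }
    if with_robustness:
        test_samples = _load_split_samples(manifest, "test")
        result["robustness"] = prediction_consistency(
            make_predict_fn(state.encoder, ft.head, infer_params),
            test_samples)
    return result


__all__ = ["PretrainConfig", "PretrainState", "RunConfig", "evaluate",
           "load_checkpoint", "make_predict_fn", "preprocess_samples",
           "pretrain", "run_experiment", "save_checkpoint", "select_kshot"]
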