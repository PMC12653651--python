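# Methods

`cropclr` implements a three-stage pipeline for pest-image classification
under scarce labels: (1) self-supervised contrastive pretraining with a
momentum encoder and a negative queue, (2) a diffusion-based consistency
filter that discards augmented view pairs whose semantics the augmentation
destroyed, and (3) few-shot fine-tuning of a class-token attention head on
the frozen backbone. This note records the model, its assumptions, the
parameters that matter, and the choices made where the design was open.

## Numerical substrate

No GPU tensor framework is assumed: the package carries a compact
reverse-mode automatic-differentiation engine over float64 numpy arrays
(`cropclr.autodiff`) with the layer/optimizer zoo built on it
(`cropclr.nn`). Every op's gradient is validated against central finite
differences in the test suite. float64 keeps closed-form loss checks exact
to ~1e-12 and makes runs bit-reproducible on one machine in single-threaded
BLAS conditions.

Backbones use group normalization instead of batch normalization: no
running statistics, identical behavior in training and inference, and no
dependence on batch composition — properties worth more at desk scale than
the small accuracy edge batch norm sometimes brings.

## Preprocessing and augmentation

Images are standardized to a square (center crop to the shorter side,
bilinear resize; zero-padding instead of cropping when the aspect ratio
exceeds 2, where a square crop would discard most of the long dimension),
default target 512×512. Color normalization equalizes the luminance channel
of a YCbCr decomposition (chroma untouched) and applies gray-world white
balance (per-channel gain = grand mean of channel means / channel mean;
equality of channel means holds exactly before the final clip to [0, 255]).

Color normalization is a robustness device of the pretraining path: it is
applied before view-pair construction so the encoder cannot shortcut on
global color statistics. It is *not* applied to fine-tune/inference inputs
by default — measured on the synthetic benchmark, inference-time
equalization costs the frozen-feature k-shot classifier roughly 20 points
of accuracy, because equalization amplifies background texture at the
expense of lesion contrast. `RunConfig.inference_color_normalize=True`
restores identical preprocessing in both paths.

Contrastive view pairs draw, independently per view: rotation
θ ~ U(−30°, 30°), horizontal flip with p = 0.5, scale s ~ U(0.8, 1.2)
(rotation applied before scaling; bilinear resampling, reflective borders),
3×3 Gaussian blur with σ ~ U(0.5, 1.5), and 1–3 rectangular cutouts with
areas uniform on [0.05·A, 0.2·A] of the image area A, filled with gray
(128) or zero. Cutout rectangles are integer-rounded so the realized area
never leaves the band. Disabling every perturbation reduces the pipeline to
standardization exactly, which the tests rely on.

## Contrastive core

The encoder is a residual convnet (`paper` profile: ResNet-50-style
bottleneck stages 3-4-6-3; `tiny` profile: three basic residual blocks for
CPU runs) followed by an affine adapter to width 512 and a two-layer
projection head 512→128→128 with an interleaved ReLU; embeddings are
L2-normalized. A momentum copy θ′ is updated only by
θ′ ← m·θ′ + (1−m)·θ with m = 0.999 and feeds a FIFO queue of K negatives
(default 4096; the canonical tens-of-thousands queue is pointless when the
whole dataset is hundreds of images). The InfoNCE loss at temperature
τ = 0.2 is one-directional (view i against view j and the queue); no
symmetrized term. Momentum embeddings are re-normalized before queueing so
queue entries stay unit-norm to 1e-6 regardless of EMA drift.

## The feature grid

The grid shared by the diffusion filter and the fine-tuning head is a
*hypercolumn*: every backbone stage's spatial output (stem included) is
bilinearly resized to the common H×W, channel-concatenated together with
its elementwise square, and 1×1-projected to C channels (defaults
16×16×128). Two measurements drove this wiring. First, per-depth linear
probes on the k-shot protocol show the deepest stage is the *least*
class-informative representation (0.60–0.62 test accuracy versus 0.87–0.98
for mid-level stages): instance-discriminative pretraining pushes the top
of the network toward image-specific detail, while the texture statistics
that separate lesion classes live in mid-level responses. Second,
class-token attention can only take weighted means over patches, so
dispersion (second-moment) statistics — the essence of texture — must be
present as explicit channels; concatenating the squared hypercolumn makes a
weighted mean able to read local variance.

## Diffusion filter

The hypercolumn grid above is the e₀ that enters the filter. Forward noising
follows q(e_t | e₀) = N(α_t·e₀, (1−α_t)·I) with the mean coefficient α_t
exactly as the formulation prints it — not the √ᾱ_t of standard denoising
diffusion; `schedule_convention="sqrt_cumulative"` switches to the standard
parameterization for interoperability. The schedule itself is unspecified
in the source formulation; the default is T = 10 with α linear from 0.95
down to 0.5, chosen so the T-term reconstruction loss stays cheap while the
terminal state is visibly corrupted.

The reconstruction net is a transformer over the H·W grid tokens (4 layers,
8 heads, FFN width 512 by default) with learned positional and additive
timestep embeddings and two tokenwise affine output branches: the mean μ and
a softplus-positive scale η. The training loss is Σ_t ‖e_{t−1} − μ(e_t, t)‖²;
η is an output-only branch because the printed objective ignores it.
Reconstruction iterates the mean path ẽ_{t−1} = μ(ẽ_t, t) from t = T.

Pair consistency is the covariance structural distance
D = 1 − Tr(Σ₁Σ₂)/(‖Σ₁‖_F‖Σ₂‖_F) between the two views' reconstructed
grids, where Σ treats the H·W positions as observations of a C-dimensional
variable. D is symmetric, 0 on identical symmetric inputs, and lies in
[0, 1] for PSD inputs (Cauchy–Schwarz under the trace inner product). The
retention threshold δ is undefined in the source; the default is
batch-quantile mode retaining the lowest 80% of distances per batch, with a
fixed-δ mode available. Filtered-out pairs are dropped from the InfoNCE term
of that step, but their momentum embeddings still enter the queue (a
dropped pair is an invalid positive, not an invalid negative). The joint
objective is L_contrast + λ·L_diff with λ = 0.5; the diffusion gradient
reaches the encoder through e₀ by default (`stop_gradient` blocks it —
measured at desk scale, the two are indistinguishable).

## Few-shot attention head

Fine-tuning freezes the backbone completely: it is run in inference mode
and its parameters never reach the optimizer. The head projects the H·W
patch features once, then N learnable class tokens (N = number of classes)
cross-attend over the patches through 3 layers of 8-head attention with FFN
128→256→128, post-layer-norm residual blocks. Patch tokens are a constant
dictionary — only the class (and optional register) tokens are updated —
which is what makes the head cheap. The concatenated class-token outputs
feed one affine layer with sigmoid outputs trained by multi-label binary
cross-entropy on one-hot targets; evaluation decodes argmax. Head training
uses momentum SGD (lr 1e-3, momentum 0.9, weight decay 5e-4), optionally
with early stopping on a held-out fold. By default the head standardizes
its input grid per channel with statistics fit on the k-shot set
(`standardize_grids`); the statistics are persisted with the head in the
checkpoint, so inference is self-contained.

Attention rows are stochastic over patches by construction. Pseudo-masks
binarize a class row at its q-quantile using the "lower" quantile method
with a ≥ rule, so the q→0 limit yields the all-ones mask exactly and ties
at the threshold are kept. Head pruning keeps the top-k heads by an
importance score defined here as the mean (over calibration samples, class
tokens and layers) of the head's maximum attention mass on any patch — how
sharply it localizes; ties break toward the lower head index, and keeping
all heads is a bitwise no-op. Pruning is applied once after fine-tuning,
before inference.

## Training schedule

Joint pretraining uses Adam at lr 1e-4, batch 32 (100 epochs at full
scale). Stage-wise training is the default: the joint contrastive+diffusion
objective in stage 1, the classification loss alone in stage 2 on the
frozen backbone — the three-term combined objective
L_contrast + λ1·L_diff + λ2·L_cls (λ1 = 0.5, λ2 = 1.0) is exposed as
`total_loss` for joint-mode experiments but is not the default schedule,
which would contradict the frozen-backbone protocol.

## Synthetic data

Field imagery of wheat pest damage is effectively private, so tests and
examples run on a procedural generator. Each class is a texture motif —
spots, stripes, blotches or rings, caricaturing feeding marks, rust-like
pustules, chlorotic patches and ring lesions — drawn in necrotic brown over
a leaf-like green background (smooth low-frequency illumination field plus
faint diagonal veins), with nuisance variation the classes do not control:
rotation up to ±15°, brightness ×U(0.8, 1.2), Gaussian blur σ ~ U(0, 1).
Everything is a pure function of (class id, spec, seed).

What the generator does and does not emulate: it produces class-conditional
texture statistics under viewpoint/illumination nuisance — enough to make
contrastive invariance and few-shot discrimination non-trivial — but no
real lesion morphology, no co-occurring infestations, no weed/soil clutter,
no sensor noise. A passing end-to-end test therefore shows the pipeline's
mechanics learn class structure under nuisance at desk scale; it says
nothing about accuracy on real field data.

## Desk-scale profile and problem sizes

The `RunConfig.tiny` profile runs the identical mechanism at reduced width:
tiny backbone (stem 16, three residual blocks), 64×64 inputs, 64-channel
8×8 feature grid, 2-layer/4-head reconstruction net, a 1-layer/4-head
fine-tuning head (the full 3-layer head overfits 30 k-shot samples badly —
0.49 versus 0.67 test accuracy in head-depth sweeps), queue 1024, and
10 pretraining epochs. The
end-to-end check trains on a 3-class, 100-images-per-class synthetic set
(70/15/15 split) for 10 pretraining epochs and a 10-shot fine-tune; the
filter-ablation comparison uses 3 seeds on a smaller 30-images-per-class
set with deliberate corruption (60% occlusion) injected into 30% of view
pairs. These sizes are the package's chosen desk-scale study conditions.

## Numerical details and edge cases

- Embedding normalization adds 1e-24 inside the square root; queue
  validation tolerates 1e-5 deviation from unit norm.
- `feature_covariance` symmetrizes (Σ + Σᵀ)/2 to kill float asymmetry;
  a single spatial position is a degenerate-input error.
- A zero covariance matrix makes the structural distance undefined and
  raises rather than returning a sentinel.
- Undefined metric ratios (zero denominators) are reported as NaN, never
  silently 0; an all-empty class is excluded from mIoU with a warning.
- Splitting uses per-class floor quotas plus largest-deficit assignment of
  the remainders, so global split sizes match the ratios to within rounding
  while every class appears in every split whenever counts allow.
- Checkpoints are a single `.npz` bundle (parameters, queue, config,
  step counter); save → load → save is byte-identical.

## Known limitations

- At a few hundred unlabeled images and tens of optimizer steps,
  momentum-contrast pretraining extracts only a modest fraction of the
  class signal a supervised run would (the supervised ceiling on the
  synthetic set is 1.0); the e2e margins reflect that reality.
- The reconstruction net is trained jointly from scratch, so early-epoch
  filtering decisions rest on a partially trained filter.
- The "paper" backbone profile builds the ResNet-50-style architecture with
  deterministic random initialization; no pretrained weights are bundled.
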