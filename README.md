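# cropclr

Self-supervised contrastive pretraining with diffusion-based view-pair
filtering and few-shot attention fine-tuning, for classifying crop pest
damage from field imagery when labels are scarce.

## The problem

Field images of wheat pest damage (feeding marks, rust-like pustules,
chlorotic patches) are cheap to photograph and expensive to label: symptoms
vary by species and growth stage, and annotation needs agronomists. Models
also face severe nuisance variation — viewpoint, illumination, blur,
occlusion by leaves — under which supervised classifiers degrade. `cropclr`
addresses both: it learns viewpoint-invariant representations from
*unlabeled* images, then adapts to the label space from as few as 5–10
labeled images per class.

## The method

**1. Contrastive pretraining.** Each image x yields two augmented views
x_i = t_i(x), x_j = t_j(x) (rotation θ ~ U(−30°, 30°), flips, scale
s ~ U(0.8, 1.2), 3×3 Gaussian blur σ ~ U(0.5, 1.5), cutouts of
0.05–0.2 of the image area, after luminance equalization and gray-world
balancing). A primary encoder f_θ with projection head g_θ embeds x_i; a
momentum copy, updated only by θ′ ← m·θ′ + (1−m)·θ (m = 0.999), embeds x_j
and feeds a FIFO queue of K negatives. The InfoNCE loss with temperature
τ = 0.2 is

    L_contrast = −log [ exp(sim(z_i, z_j)/τ) / (exp(sim(z_i, z_j)/τ) + Σ_k exp(sim(z_i, z_k⁻)/τ)) ].

**2. Diffusion-based pair filtering.** Aggressive augmentation sometimes
destroys the content that made the pair "positive". The encoder's spatial
feature grid e₀ is noised along a schedule, q(e_t|e₀) = N(α_t·e₀, (1−α_t)I),
a transformer decoder learns the reverse mean path under
L_diff = Σ_t ‖e_{t−1} − μ_θ(e_t, t)‖², and each pair is scored by the
covariance structural distance of its two reconstructed grids,

    D_struct = 1 − Tr(Σ₁Σ₂) / (‖Σ₁‖_F ‖Σ₂‖_F)  ∈ [0, 1].

Pairs with D_struct below the retention threshold stay in the contrastive
loss; the joint pretraining objective is L_contrast + λ·L_diff (λ = 0.5).

**3. Few-shot attention fine-tuning.** The backbone is frozen. N learnable
class tokens cross-attend over the patch features of the grid
(softmax(QKᵀ/√d_k)V), their outputs feed a sigmoid classifier trained with
multi-label binary cross-entropy on k images per class; argmax decodes the
label. Attention rows double as pseudo-masks; heads can be pruned to the
top-k by attention mass.

Real pest datasets of this kind are private, so the package ships a
deterministic procedural generator: per-class texture motifs (spots,
stripes, blotches, rings) on leaf-like backgrounds with illumination, blur
and viewpoint nuisance. See `docs/methods.md` for every modelling choice,
parameter and limitation.

There is no GPU dependency: the networks run on a small reverse-mode
autodiff engine over float64 numpy arrays that is part of the package
(`cropclr.autodiff`, `cropclr.nn`), with gradients finite-difference-tested.

## Worked example

Generate a 3-class synthetic dataset, split it 70/15/15, pretrain the
desk-scale profile, fine-tune with 10 labeled images per class, and
evaluate:

    cropclr generate-data --classes 3 --per-class 100 --size 64 --seed 0 --out data/
    cropclr split --manifest data/manifest.csv --ratios 0.70,0.15,0.15 --seed 0
    cropclr init-config --profile tiny --classes 3 --out tiny.yaml
    cropclr pretrain --config tiny.yaml --data data/manifest.csv --seed 0 --out ckpt.npz
    cropclr finetune --checkpoint ckpt.npz --data data/manifest.csv --kshot 10 --out ckpt_ft.npz
    cropclr evaluate --checkpoint ckpt_ft.npz --data data/manifest.csv --split test

With the tiny profile's 10-epoch default this prints (abridged):

    wrote 300 images to data/
    split sizes: {'train': 210, 'val': 45, 'test': 45}
    pretrained 10 epochs; final {'joint_loss': 26632.3, 'contrast_loss': 6.91,
      'diffusion_loss': 53250.9, 'retention': 0.781}
    fine-tuned on 10×3 samples for 200 epochs; final loss 0.0198
    {
      "accuracy": 0.8666666666666667,
      "macro_precision": 0.8653846153846154,
      "macro_recall": 0.8666666666666666,
      "n": 45
    }
    confusion matrix (rows=truth):
      11    2    2
       1   14    0
       1    0   14

Reading this: pretraining kept ~78% of view pairs per batch (the
batch-quantile filter drops the least consistent 20%), and the 10-shot
classifier reaches 87% test accuracy on a 3-class problem whose chance
level is 33%. The diffusion loss dwarfs the contrastive term because it is
a squared Frobenius norm summed over a 64-position × 64-channel grid and
T = 10 timesteps — the balance λ = 0.5 weights its *gradient*, which Adam
renormalizes per-parameter.

`cropclr robustness --checkpoint ckpt_ft.npz --data data/manifest.csv`
reports the viewpoint-perturbation protocol; on the checkpoint above it
prints a prediction consistency of 0.819 and a confidence variation of
0.139 over rotations up to 50°, occlusion, and brightness shifts.

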