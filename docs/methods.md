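# Methods

## Problem and model

`sonomil` implements a two-stage deep-learning pipeline for predicting
axillary lymph node (ALN) metastasis in breast cancer from a patient's
multi-view B-mode ultrasound examination: M >= 1 views of the primary
tumor plus N >= 0 views of axillary nodes (N = 0 when no node is visible
sonographically).

**Stage 1 — image-level multi-task network.** A backbone maps each
grayscale view to a feature map `z` at stride 16. A light mask decoder —
two *two-way attention* blocks that alternate (i) mask-token
self-attention, (ii) token-to-image cross-attention, (iii) a token
feed-forward layer and (iv) image-to-token cross-attention — refines `z`
and a single learnable mask token. The image branch is upscaled by two
stride-2 transposed convolutions to the stride-4 segmentation feature
`s`; the token is mapped by a two-layer MLP and dotted with `s` at every
location, giving the segmentation probability map
`ŷ_seg = σ(⟨MLP(token), s⟩)`, bilinearly upsampled to input resolution.
The predicted map then acts as a soft attention gate:

    z_m = s ⊙ pool(ŷ_seg)      (input to the lesion-type head)
    z_c = z ⊙ pool(ŷ_seg)      (input to the metastasis head)

where `pool` is area-average pooling to the feature's resolution. Both
heads are global average pooling followed by a 1x1 convolution and a
sigmoid. Three binary cross-entropies are optimized jointly (weights
1:1:1 by default): segmentation against the rasterized outline,
lesion-type (tumor vs node), and an image-level metastasis objective
whose targets are *pseudo-labels*: every image inherits its patient's
label, including tumor views of node-positive patients. The gate is
**not** detached, so the classification losses shape where the attention
map opens; the pseudo-label noise on tumor views is absorbed by stage 2.

**Stage 2 — patient-level multi-instance learning.** With stage 1
frozen, each view contributes one token: a linear projection (to d = 256)
of the spatially averaged gated feature `z_c`. A patient's tokens form a
bag of size M + N; a learnable CLS token is prepended and a small
pre-norm transformer encoder (no positional embeddings — bag order is
clinically meaningless, making the model exactly permutation-invariant)
mixes the bag. Padded batch slots are excluded from attention, so
padding is exactly invisible. The final CLS embedding passes through a
two-layer MLP and a sigmoid; training is BCE on the patient label.
Patients with N = 0 are scored like any other bag.

**Interpretation.** Because the metastasis head is pool-then-linear, the
class activation map (CAM) is exact: the raw map is the weighted channel
sum of `z_c` under the head weights, and its spatial mean equals
`logit − bias`. Maps are rectified then min-max normalized per image
(negative evidence is not displayed). Localization is quantified by the
*lesion mass fraction* — the share of CAM mass inside the ground-truth
outline — compared against the lesion's area fraction.

## Evaluation statistics

- ROC AUC as the Mann-Whitney statistic (ties count 1/2), with DeLong
  structural-component variance for confidence intervals and the paired
  DeLong test for correlated AUCs (`z = ΔAUC/SE`, two-sided normal `p`;
  identical score vectors return `p = 1` exactly).
- Threshold metrics at 0.5 (Youden-on-validation optional): accuracy,
  sensitivity, specificity, PPV, NPV, F1, and the mistake / omission
  diagnostic rates defined as `1 − specificity` / `1 − sensitivity`.
- Precision-recall with step-integrated average precision.
- Decision curve analysis: `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)` with
  treat-all and treat-none references.
- Segmentation mIoU: per-image foreground IoU averaged over images
  (empty-∪-empty counts as 1); a background-inclusive two-class mean is
  available by flag.
- Pearson chi-square without continuity correction by default (a Yates
  flag exists); cohort-characteristic tables of the reference study are
  bundled in `reference_cohorts`.
- Clinical baseline: maximum-likelihood logistic regression on one-hot
  BI-RADS grade (reference 4A) and clinical T stage (reference T1), with
  a ridge-stabilized fallback (and warning) under separation.

## Numerical core

No GPU tensor framework is used: the networks run on a compact
reverse-mode autodiff engine over float64 numpy arrays
(`sonomil.autograd`), providing exactly the operations the models need
(strided convolution via im2col, kernel-2/stride-2 transposed
convolution, area pooling, half-pixel bilinear upsampling, masked
multi-head attention, softmax, BCE with 1e-7 probability clamping).
Every operation is verified against central finite differences in the
test suite. Optimization is AdamW (decoupled weight decay 0.01, constant
learning rate; no schedule, with a configurable hook point).

## The phantom cohort generator

Real cohorts are private, so the generator plants the sonographic signs
the framework is designed to exploit into controllable speckle phantoms:

- **Texture**: a unit-mean gamma speckle field (sd `speckle_scale`,
  default 0.35) smoothed by a Gaussian kernel (radius 1.2 px) multiplies
  a deterministic intensity profile, clipped to [0, 1].
- **Lesions**: one per view; a rotated ellipse whose radius is perturbed
  as `r(θ) = base(θ)·(1 + irregularity·sin(kθ + φ))`, k ∈ {3..7};
  interiors darkened by `lesion_contrast` (0.5) — hypoechoic on a 0.5
  background.
- **Nodes**: benign nodes are elongated (axis ratio 0.40-0.55) and carry
  a bright central hilum disc (+0.3 contrast) with probability 0.95;
  metastatic nodes lose the hilum (probability drops by
  `hilum_loss_gap`, default 0.9), become rounder (`roundness_shift`
  0.3) and more irregular (`irregularity_shift` 0.2).
- **Tumor views**: views of metastatic patients get a mild size and
  irregularity shift (`tumor_signal_shift`, default 0.12) — chosen so
  tumor-only prediction is informative (view-level AUC ≈ 0.6-0.7) but
  clearly weaker than node views (≈ 0.95), matching the clinical
  ordering in which single-view tumor models underperform the two-stage
  design.
- **Labels and bags**: a latent uniform metastasis score thresholded at
  `1 − prevalence` (default prevalence 0.642, the reference training
  cohort rate) defines the label; node-view visibility is
  label-dependent (0.9 positive / 0.7 negative) since suspicious nodes
  are more often seen. Setting all effect shifts to zero makes every
  image statistically independent of the label; the null-control
  experiments additionally equalize node visibility so bag composition
  carries no signal either.

Generation is counter-seeded per patient (`SeedSequence((seed, i))`), so
cohorts are byte-identical across runs and machines. Ground-truth
outlines are produced by tracing the half-level contour of the rendered
mask and simplifying it (round-trip rasterization IoU >= 0.95), in the
LabelMe JSON dialect; pixel centers sit at integer coordinates, x right,
y down, and rasterization uses the even-odd rule with boundary pixels
included.

**What the phantoms do not emulate**: acoustic shadowing and
enhancement, depth-dependent gain, anisotropic speckle, multi-lesion
views, operator variability, or inter-vendor appearance differences.
Passing desk-scale tests therefore demonstrates that the *mechanisms*
(gating, bag pooling, evaluation statistics) work as specified — not
that the pipeline reaches clinical performance on real images.

## Profiles and problem sizes

The `paper` profile carries the published hyperparameters: 512x512
inputs with scale jitter 0.8-1.25, random 512 crop and 50% horizontal
flip; AdamW at 6e-5; 16 images per stage-1 step for 10k iterations;
4 patients per stage-2 step for 100 epochs; 256-d tokens. Running it
requires hardware and data beyond this package's scope.

The `desk` profile is the package's own first-class configuration and
the one every quantitative test uses: 96x96 phantoms, the tiny 4-stage
convolutional backbone (~57k parameters; an attention backbone of
similar size is provided under the same contract), 2000 stage-1
iterations at learning rate 2e-3, 100 stage-2 epochs at 1e-3, and no
augmentation (phantoms have no acquisition-domain shift to augment
away, and the jitter slows convergence at this scale). The benchmark
cohort is 400 patients split chronologically 300 train / 100 test; the
null control uses 360 patients with 600 stage-1 iterations (nothing
label-linked exists to learn there), and the tumor-only ablation trains
full-bag and tumor-only stage-2 models identically (40 epochs) at three
seeds. End to end, the benchmark — planted run, ablation, null control
and CAM scoring — takes roughly 16 minutes on one CPU core.

## Design choices where the design was open

- **Pseudo-labels** broadcast the patient label to all its views; the
  simplest rule consistent with patient-level supervision.
- **Crop padding** (train mode): zero-padding when the jittered resize
  falls short of the crop size; interpolation is bilinear for images and
  nearest for masks.
- **Stage coupling**: stage-1 weights are frozen during MIL training;
  joint fine-tuning is out of scope.
- **mIoU** averages per image rather than pooling pixels over the
  dataset, so small lesions are not swamped by large ones.
- **Chi-square** uses no continuity correction at any table size by
  default; the bundled reference tables reproduce the published
  three-decimal p-values under this convention.
- **Omission rate** is defined as `1 − sensitivity` (the definitional
  identity), and the threshold convention is score >= threshold.
- **"Unknown"** invasion-status categories are retained as ordinary
  levels in contingency tables.
- **Checkpoint compatibility** is enforced by a config hash stored in
  both stages' archives; predicting with mismatched stages is an error.

## Known limitations

- The engine is CPU-bound and float64; the paper profile is declared,
  not exercised.
- The single mask token yields semantic (single-lesion) segmentation;
  multi-lesion views are out of scope, matching the one-lesion-per-view
  phantom convention.
- The MIL stage offers no instance-level attribution beyond per-image
  stage-1 probabilities and CAMs.
- Null-effect AUC on ~90 test patients has a standard error of ≈ 0.06;
  its acceptance band [0.40, 0.60] is a statistical statement, not an
  exact identity.
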