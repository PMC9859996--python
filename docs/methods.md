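# Methods

## Problem and model

Routine breast-ultrasound screening produces mostly lesion-free (normal)
B-mode images. A segmentation network trained in the usual way — on
tumor-containing images only, or even on mixed data without an explicit
normal/abnormal signal — tends to hallucinate lesion masks on normal
images, because nothing in its training objective distinguishes "no
lesion anywhere" from "lesion here". `busgate` implements a two-branch
architecture that addresses this directly:

- **Segmentation branch.** A U-shaped encoder-decoder with DenseNet-style
  blocks. The encoder has four dense blocks (3, 4, 8 and 12 conv blocks in
  the reference configuration) separated by three transition-down stages
  (1x1 compression convolution, factor 0.5, then 2x2 max pooling); the
  decoder has three dense blocks (8, 4, 3) each preceded by a
  transition-up stage (1x1 compression then 2x upsampling, bilinear by
  default) and a concatenation with the same-scale encoder skip features.
  Each conv block is BN → ReLU → 1x1 bottleneck conv → BN → ReLU → 3x3
  conv emitting `growth_rate` channels, densely concatenated. A final 1x1
  convolution produces per-pixel lesion logits at input resolution.
- **Classification branch.** Attached to the last encoder feature map:
  one conv block (same design), global average pooling, and a fully
  connected layer producing an image-level normal/abnormal logit. The two
  branches share the encoder.
- **Gate.** At inference, if `sigmoid(class logit) < cls_threshold`
  (default 0.5) the predicted mask is forced empty. The decoder is still
  executed and its output discarded — this keeps batching branch-free and
  honors the gate at the output contract.

### Loss

Per batch: `L = cls_weight · BCE(class logit, label) + BCE(y, t) +
Dice(y, t)` with `Dice(y, t) = 1 − (2Σyt + 1)/(Σy + Σt + 1)` on the
sigmoid probability map y and binary mask t. Pixel BCE is reduced by the
mean rather than the printed sum so magnitudes are comparable across
image sizes and with the Dice term (the summed form is available via
`reduction="sum"`). The two branches are equally weighted
(`cls_weight=1`) in the absence of any stated weighting. Lesion-free
images contribute segmentation loss against the all-zero mask by default
(`apply_seg_loss_to_normals`), i.e. normals are informative negatives
for the decoder as well as for the classifier; a flag disables this for
the ablation. Probabilities are clamped to `[1e-7, 1 − 1e-7]` before
logarithms in the functional (probability-space) implementation; the
training path evaluates BCE directly on logits in the numerically stable
form.

### Metrics

Generalized DSC `(1 + 2|Am∩Ar|)/(1 + |Am| + |Ar|)` is defined for every
image: on a lesion-free image it reduces to `1/(1 + |Ar|)`, so a correct
empty prediction scores 1 and spurious area is penalized. JI, TPR, FPR
and FNR follow the set formulas and are undefined (reported as
missing-with-reason, never 0) when the ground truth is empty; FPR =
|Ar∖Am|/|Am| is deliberately not clipped and can exceed 1. TPR + FNR = 1
is an algebraic identity and is asserted over random mask pairs.

Boundary metrics: a contour pixel is a foreground pixel with at least
one background 4-neighbor, the image border counting as background (the
simplest testable convention; no convention is standard). HE is the
symmetric Hausdorff distance between the two contour pixel sets; MAE
pools the directed nearest-neighbor distances of both contours and
averages them (a directionless reading of "average disagreement"; the
max-of-directed-means alternative is available via `mae_mode`). Both are
computed with a k-d tree and verified against an all-pairs brute-force
oracle in the tests. Distances are in pixel units (`pixel_spacing`
defaults to 1).

Classification metrics (AUC, sensitivity, specificity, accuracy, F1) are
computed with scikit-learn, abnormal being the positive class; AUC is
flagged undefined on single-class label sets.

### Training protocol

Adam, initial learning rate 0.001, no schedule, no weight decay, no
early stopping. k-fold cross-validation (default k=10): a seeded shuffle
partitions records into folds differing in size by at most one
(`grouping="image"`); `grouping="patient"` instead assigns whole
patients greedily to the smallest fold, preventing leakage when one
patient contributes several images — both modes exist because image
datasets rarely state which was used and the two answer different
questions. Each rotation trains on k−1 folds and keeps the epoch
checkpoint with the highest validation generalized DSC, averaged over
*all* validation images including normals (the headline metric is
defined there, and it is precisely the normal images the gate is meant
to fix). Fold metrics are reported as mean ± SD across rotations.
Augmentation is random horizontal flipping of image and mask together
(probability 0.5 per sample per epoch — the conventional rate). All
randomness (weights, shuffling, flips) derives from one integer seed;
training is single-threaded and bit-reproducible.

Ablation variants: `full` (gated two-branch network, all images),
`model2` (classification branch deleted, all images), `model2_pos`
(branch deleted, lesion-free images removed from the training side of
every rotation — the common tumor-only regime).

## Numerical backend

The network runs on a compact reverse-mode autodiff engine written on
numpy (NHWC layout, float32): convolution as a sum of shifted GEMMs (one
per kernel tap — faster than im2col on one core, where the unrolled-column
copy is memory-bound), single-pass batch-norm statistics, argmax-routed
max-pool gradients, separable bilinear 2x upsampling with an exact
adjoint, and bias-corrected Adam. Every backward rule is checked against
central finite differences, and the convolution forward pass against
scipy's `correlate2d`. Weight initialization is He fan-in from an
explicit seeded generator; there is no global RNG state.

## Synthetic phantoms

The phantom generator supplies the study conditions. Each image is a
smooth echogenic background (clipped Gaussian random field) times
multiplicative unit-mean gamma speckle (shape 4 by default). An abnormal
image carries one hypoechoic lesion: an ellipse whose radius is modulated
by a low-order random Fourier series — amplitude `boundary_irregularity`
spans smooth benign-like (x0.5) to lobulated malignant-like (x2, and
x0.8 contrast) shapes — darkened multiplicatively by `lesion_contrast`
(default 0.5), with the footprint bisected so its area always lies in
`lesion_area_range` (3–12% of the image). A posterior acoustic shadow
band is added below the lesion with probability 0.3.

Both normal and abnormal images additionally contain **distractors**:
unannotated hypoechoic structures (count ~ Poisson(0.8), contrast
0.60–0.85, area 1–4%, placed off the lesion) standing in for the
shadows, vessels and fat lobules that make real lesion-free images
nontrivial. Without them, lesion-free phantoms are pure speckle, a
segmentation-only model never false-positives on them, and the
normal-image failure mode the gate exists to fix cannot occur in the
synthetic world at all; their contrast and size were chosen once to be
clearly weaker and smaller than lesions so that image-level labels
remain learnable.

What the phantoms do *not* model: acoustic point-spread functions,
depth-dependent attenuation or focus, anatomy (ribs, pectoral muscle,
skin layers), correlated speckle, probe pressure, or temporal coherence
of distractors across sweep frames. Passing benchmarks on phantoms
therefore demonstrates that the architecture, losses, gating and
protocol behave as designed — not clinical performance.

Sweep sequences for the screening simulation translate a fixed lesion
shape horizontally across the field of view between an entry and an exit
frame; frames outside that window are lesion-free. Frames are segmented
independently (no temporal smoothing), and the simulation reports
false-positive lesion-free frames and the fraction of lesion frames
whose predicted mask overlaps the truth.

## Desk-scale sizes and defaults

The reference block structure (3/4/8/12 and 8/4/3) is always used, but
channel widths are CPU-scale by default: `growth_rate=6`,
`initial_channels=12`, bottleneck factor 2 (the estimator's defaults;
`NetworkConfig` itself defaults to 16/32/4 for larger runs). Width is a
free knob of this architecture family; these values keep a full training
run on one core in minutes at 64x64 while leaving the structure under
test identical. The standard benchmark (`run_desk_benchmark`) trains on
200 phantoms at 64x64 (half normal) for 15 epochs with batch size 8 and
evaluates on 60 held-out phantoms; it is the package's scaled-down
analogue of the clinical ablation: the gated model keeps the normal-image
generalized DSC near 1 where the tumor-only baseline collapses, at
matched abnormal-image sensitivity.

Degenerate inputs: empty masks yield flagged-undefined boundary metrics
and positive-image metrics; empty-vs-empty Dice loss and generalized DSC
are exact zeros/ones by the +1 smoothing; single-class label sets flag
AUC undefined; aggregation excludes undefined entries and reports
exclusion counts.

## Known limitations

- Phantom realism as above; no claim of clinical transfer.
- The gate is a hard output-level switch; probabilistic blending or
  skipping the decoder computationally are not implemented.
- `model2_pos` shares the fold split with the other variants before its
  training-side filtering, so its effective training sets are smaller,
  exactly as in the tumor-only regime it reproduces.
- The numpy backend targets clarity and reproducibility over speed; it
  is single-threaded and has no GPU path.
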