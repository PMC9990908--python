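# Methods

`embryoseg` is a desk-scale implementation of a whole-body multi-organ
segmentation pipeline for contrast-enhanced fetal mouse micro-CT: a
UNETR-style network trained with a combined Dice + cross-entropy
objective, sliding-window inference with overlap blending, Dice-based
evaluation, connected-component ("island") cleanup, and volumetric
phenotyping of organ volume fractions between cohorts. Because full-scale
training requires a GPU and a large annotated atlas dataset, every stage
is exercised end-to-end on synthetic embryo phantoms with exact labels;
the architecture and procedures are size-configurable so the full-scale
settings remain expressible.

## Model

The input crop (default 128³ voxels, single grayscale channel) is divided
into non-overlapping P³ patches (default P = 16), each flattened and
linearly projected to a K-dimensional embedding (default K = 768). A
learnable 1D positional embedding is added and the sequence passes
through L pre-norm transformer blocks (default L = 12, 12 heads, MLP
ratio 4, GELU). Hidden states at depths `skip_layers` (default {3, 6, 9,
12}; the deepest is the bottleneck) are reshaped onto the patch grid and
decoded convolutionally: the bottleneck enters through a 2× transposed
convolution, intermediate skips through chains of 2× deconvolutions with
3×3×3 convolution blocks (instance norm + leaky ReLU), and the raw crop
through a full-resolution convolution block. Decoder stages concatenate
the upsampled path with the matching skip, convolve, and upsample again;
a final 1×1×1 convolution with a softmax yields per-voxel probabilities
over C classes at the input resolution. Decoder widths are
`feature_size × 2^s` at resolution /2^s. The skip depths, head count,
norm layers and decoder widths are deliberate design choices where the
overall architecture family leaves them open; all are configurable.

The `tiny()` preset (P = 8, K = 64, L = 4, heads 4, skips {2,3,4},
feature size 8, input 64³, ~0.4 M parameters) trains in minutes on one
CPU core and is used throughout the test pipeline.

The loss is `0.5 * soft-Dice + 0.5 * cross-entropy`. Soft Dice per class
is `(2·Σ p·g + ε) / (Σ p + Σ g + ε)` with ε = 1e-5, averaged over all
classes including background (a documented, switchable choice); the
cross-entropy is the mean per-voxel negative log probability of the true
class. Both terms vanish in the perfect one-hot limit.

### Numerical engine

No GPU tensor framework is assumed: the network runs on a small
reverse-mode autodiff engine over numpy (`embryoseg.autodiff`).
Convolutions are evaluated as one GEMM per kernel offset on strided
views (merged into a single column-matrix GEMM when the input channel
count is small), which keeps peak memory flat; the input gradient is
computed as a correlation with the spatially flipped, channel-swapped
kernel to avoid scatter-adds. The engine is dtype-transparent; gradient
checks run in float64, training in float32. All operator gradients are
verified against central differences in the test suite.

## Training

Volumes are normalized to zero mean / unit variance over the whole
volume (the same normalization is applied before inference). Training
samples random cubic crops uniformly over valid offsets; because small
phantoms are background-dominated, a foreground-biased mode (retry until
the crop contains foreground, bounded) is on by default. Augmentation
applies one sampled instance of: rotation (uniform per-axis angles),
affine scale/shear, intensity shift, and Gaussian noise; spatial
transforms are shared between image and labels (labels resampled
nearest-neighbor), intensity transforms touch the image only.

Optimization is AdamW (β = 0.9/0.999, weight decay 1e-5, batch size 1 —
batch size, weight decay and the absence of a learning-rate schedule are
explicit choices where the procedure is otherwise unspecified; optional
global gradient-norm clipping is available). The full-scale schedule is
80,000 iterations at lr 1e-4 with validation every 500 steps. The tiny
preset runs a few hundred iterations with a much hotter, clipped
optimizer (lr 1e-2, β = 0.9/0.95, gradient-norm clip 1.0): at miniature
width the conservative full-scale rate stalls in a long
background-dominated plateau before the small structures are picked up,
and the faster second-moment decay plus clipping removes that plateau
without destabilizing the run. The tiny preset also initializes the
output layer's bias to the empirical log class priors of the training
labels, which gives rare structures balanced gradients from the first
step and eliminates a failure mode where one small organ class never
escapes an all-background prediction. Every `val_interval` steps the validation volumes are segmented by
full sliding-window inference and the mean foreground Dice recorded; the
returned checkpoint is the best-validation one (final checkpoint when no
validation set is given). Training is fully deterministic given the
config seed on a fixed platform. `stop_at_val_dice` optionally ends the
run once a validation target is reached.

## Inference

Sliding windows of the model's input size cover the (padded) volume with
stride `max(1, floor(window·(1−overlap)))`, the final window clamped to
the volume edge so every voxel is covered; the full-scale setting is
window 128, overlap 0.8. Window probabilities are accumulated under a
blend profile — Gaussian (σ = window/8, floored at 1e-4) by default to
suppress edge artifacts, constant for exact-averaging oracles — then
normalized by the accumulated weight. Labels are the per-voxel arg-max
with ties broken toward the lower class ID (background wins ties).
Volumes shorter than the window on any axis are zero-padded at the high
end and un-padded afterwards. Whole-volume (not per-window)
normalization is used, matching training.

## Evaluation and phenotyping

Dice is `2|A∩B|/(|A|+|B|)` per label; two empty masks score 1.0 (the
structure is correctly absent), flagged in reports and excludable.
Island removal computes 26-connected components per label and either
keeps only the largest (ties: the component containing the lowest linear
voxel index) or drops components below a size threshold; removed voxels
become background. Volume fractions are
`100 · voxels(label) / voxels(all foreground)`; whole-body volume is the
union of foreground labels (atlas labels tile the body), overridable
with an explicit body-mask label. Group comparison runs a two-sided
pooled-variance Student's t-test per label with significance `p < α`
(α = 0.05 default); no multiple-testing correction by default, matching
per-label reporting conventions, with an optional Holm correction. Zero
pooled variance with equal means yields p = 1 by convention.

## Phantoms

The generator emulates an iodine-stained embryo scan: an air background
(intensity 0), a smooth perturbed ellipsoidal body envelope of soft
tissue (intensity 100), and `n_organs` ellipsoidal organs with distinct
mean intensities spread over 150–250 arbitrary units, plus a smooth bias
field (amplitude 4), Gaussian noise (σ = 5) and a low-frequency random
deformation (4³ control points, cubic upsampling, RMS amplitude 1.5
voxels) applied identically to intensities (trilinear) and labels
(nearest-neighbor). Canonical organ radii form a decreasing geometric
sequence over 5–14% of the smallest grid axis, so low label IDs are
large liver-like structures and the highest IDs small adrenal/thymus-like
ones. Cohort members share the canonical layout and jitter position
(σ = 1.5 voxels), size (volume CV 10%), orientation, anisotropy
(volume-preserving, ±25%) and intensity (σ = 4) per specimen — values
chosen as a plausible miniature of inter-individual anatomical variation.
"Knockout" cohorts scale selected organs' linear dimensions by
factor^(1/3) before rasterization and deformation, so organ volume
scales by ≈ factor while all random draws stay aligned with the paired
baseline specimen.

What the phantoms do **not** emulate: real anatomy (organ shapes are
smooth ellipsoids with far crisper boundaries than tissue interfaces),
X-ray physics (no beam hardening, partial-volume or reconstruction
artifacts), contact between organs, or the 50-structure atlas complexity
of a real whole-body label set. Passing tests therefore demonstrate that
the pipeline's machinery — optimization, windowed inference, scoring,
statistics — behaves correctly at scale-model size, not that the network
reaches any particular accuracy on real micro-CT data.

## Problem sizes

The shipped configurations are deliberately desk-scale: phantoms default
to 64³ voxels with 10 organs (48³ with fewer organs in the fastest
paths), the tiny network preset is used for all training tests, training
runs are a few hundred iterations, and cohort statistics use group sizes
of 11 vs 8 (the sizes of the emulated experiment) over 20 replicates.
The full-scale defaults (128³ crops, K = 768, 80,000 iterations, overlap
0.8) remain the configuration defaults so the package states the real
procedure; they are simply not exercised by the tests.

## Known limitations

- Single-channel input and cubic crops only; no resampling of
  anisotropic spacing (the network operates in voxel space).
- Batch size 1 training; no LR schedule, mixed precision, or multi-GPU.
- CPU-only arithmetic: full-scale (K = 768, 128³) training is out of
  reach; the full-scale configuration is expressible but impractically
  slow without hardware acceleration.
- The shipped 10-organ label table is a phantom convention, not the
  50-structure atlas of the real dataset, whose exact ID↔name table is
  user-supplied.
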