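# Methods

## Problem setting

Lower-grade gliomas are hyperintense on FLAIR MRI. Given a 2-D slice
(stored as a 3-channel 8-bit image or a DICOM file) the pipeline produces a
binary lesion mask and converts it to a physical area in mm² using the pixel
spacing from the image metadata. The package implements the full chain —
preprocessing, segmentation (classical and learned), evaluation, area
quantification — together with a synthetic phantom generator that makes every
stage testable against analytic ground truth.

## Networks

All three architectures are fully convolutional encoder–decoders with skip
concatenations and a 1×1 convolution + sigmoid head; inputs are H×W×3 grids
in [0,1] with H, W divisible by 16.

**Classic U-Net.** Encoder stages of two 3×3 ReLU convolutions at widths
64/128/256/512 with 2×2 max-pooling, a 1024-wide bottleneck, and a mirrored
decoder using 2×2 stride-2 transposed convolutions. No batch normalization.
31,031,745 trainable parameters.

**VGG19 U-Net.** The 16-convolution VGG19 stack as encoder. Skip tap-offs
are the last convolution of blocks 1–4; the block-5 output (after pool-4,
at 1/16 resolution) is the bridge, so five encoder feature maps feed the
decoder and VGG19's fifth pool is never applied. The decoder uses standard
transposed convolutions and two batch-normalized 3×3 convolutions per stage
at widths 512/256/128/64; the 16 batch-norm layers contribute
2·2·(512+256+128+64) = 3840 non-trainable moving statistics.

**Lightweight CBAM separable U-Net** (the package's center piece). The same
VGG19 encoder, trainable, with dropout (rate 0.2) after each block. Each of
the four decoder stages is:

1. depthwise-separable 2×2 stride-2 transposed convolution (depthwise
   upsampling then a pointwise channel mix) to the stage width;
2. concatenation with the encoder skip;
3. CBAM refinement of the concatenated map — channel attention (shared
   two-layer MLP over average- and max-pooled descriptors, reduced width
   `max(1, C/r)`) then spatial attention (k×k convolution over the
   channel-wise average and max maps), both sigmoid-gated;
4. six separable convolution units (depthwise 3×3 → pointwise 1×1 → batch
   norm → ReLU), the first mapping the concatenated channels down to the
   stage width.

The bottleneck is a pass-through of the block-5 features: with a trainable
encoder an extra mixing block there adds parameters without measurable
benefit at desk scale.

### Why widths 128/64/32/16 with six units and reduction ratio 16

The design goal for the lightweight model was a decoder budget of roughly
0.3–0.4M trainable parameters on top of the 20,024,384-parameter VGG19
stack, with batch-norm moving statistics summing to 2·(BN channels) = 2880.
Those two constraints interact: wider stages with fewer units (e.g.
256/128/64/32 with three units, the same 1440 BN channels) blow the budget —
the concat→width pointwise at stage 1 alone costs (512+256)·256 ≈ 197k and
the transposed-conv pointwise another 131k, pushing the decoder past 600k.
Halving the widths and doubling the unit count keeps the same BN-channel sum
while the quadratic pointwise terms shrink fourfold. With CBAM applied to
the concatenated map, a reduction ratio of 16 keeps the four attention MLPs
at 70k parameters total. The shipped configuration lands at 395,832 decoder
parameters — 20,420,216 trainable in total — and exactly 2880 non-trainable.
All of these are `ModelConfig` knobs, not constants.

### Initialization

* Convolutions and dense layers: He-normal, biases zero.
* Head bias: `logit(foreground_prior)` with prior 0.1, so the initial
  probability map matches a realistic lesion fraction instead of 0.5. This
  is the standard prior-aware initialization for class-imbalanced dense
  prediction; it removes the early training phase that merely suppresses
  background.
* Decoder convolutions are scaled by `decoder_init_gain = 0.05` after He
  initialization. Every decoder convolution is followed by batch
  normalization, which makes the forward pass invariant to that scale; the
  benefit is optimizer dynamics: with a small, bounded-step optimizer
  (Adamax moves each weight by at most ≈ lr per step) a weight of magnitude
  ~0.01–0.05 can be completely re-oriented within a few hundred steps,
  whereas a weight at full He scale (~0.3) cannot. The gain is a config
  field; setting it to 1.0 restores plain He initialization.

### Width multiplier

`width_multiplier` scales the encoder trunk (each VGG19 width is replaced
by `max(1, round(w·m))`); the decoder is sized directly through
`decoder_widths`. The classic U-Net, whose decoder mirrors its encoder,
scales end to end. The multiplier exists to make desk-scale smoke models:
at 0.125 the conv-dominated parameter count shrinks by ≈ (1/8)².

### Parameter census and FLOPs

`count_parameters` partitions exact integer counts by trainability:
trainable = weights with gradients; non-trainable = frozen weights plus
batch-norm moving statistics. FLOPs are analytic, computed layer by layer
at build time for one forward pass at the configured input size, counting
multiply and add separately (2 ops per MAC). Published FLOP figures for
comparable models vary by orders of magnitude depending on the counting
tool; no claim is attached to the absolute number beyond this stated
convention.

## Training

Soft-Dice loss `1 − (2Σpo + ε)/(Σp + Σo + ε)` with ε = 1.0 (stabilizes
empty masks; configurable), averaged per sample over the batch. Adamax with
bias-corrected first moment, β₁ = 0.9, β₂ = 0.999, eps = 1e-7, initial
learning rate 0.00025, batch size 40, up to 150 epochs. Early stopping
watches validation accuracy by default (validation Dice is offered because
pixel accuracy saturates near 1 on class-imbalanced masks): the first
observed value counts as an improvement, so a flat monitor stops training at
epoch patience+1; the best-monitor state (parameters and buffers) is always
restored. Batch order reshuffles each epoch from the config seed;
single-threaded runs are reproducible. A non-finite loss aborts with a
diagnostic. `mixed_precision` casts the model to float32 compute (off by
default; models are float32 natively, float64 is available for gradient
checking).

Batch normalization uses momentum 0.9 in the decoders so that moving
statistics converge within short desk-scale runs; eps = 1e-5.

## Classical thresholding

Pixels equal to the threshold are foreground, mirroring the ≥ branch of the
thresholding rule, consistently in `apply_threshold` and in the class means
of the isodata iteration. Isodata starts from the global mean (the
conventional initial split), stops when the threshold moves ≤ 0.5 intensity
levels (below 8-bit quantization; configurable), and provably terminates on
discrete images within the 256-iteration cap. Otsu scans every distinct
observed level above the minimum (so neither class is empty), maximizing
between-class variance with ties broken toward the lowest level; the
within/between decomposition of total variance is used as a self-check and
holds to 1e-9 relative. Constant images raise a degenerate-histogram error
in both methods.

## Preprocessing

* Normalization: per-image min–max to [0,1]; a constant image maps to zeros
  with a logged warning (the formula is 0/0 there).
* Resizing: nearest-neighbor for image and mask; pixel spacing is rescaled
  by (original/target) per axis so the slice keeps its physical extent.
* Splitting: seed-deterministic shuffle, floor(n·fraction) for train and
  validation, remainder to test; default 70/15/15. Splits are at slice
  level — with real multi-slice patients a patient-level split would be
  required to avoid leakage; phantoms are independent so the caveat is moot
  here.
* Augmentation: both described schemes are implemented. The fixed
  enrichment scheme produces 45°/90°/135° rotations plus both axis flips;
  90° multiples are exact pixel permutations (`rot90`), other angles
  interpolate bilinearly with nearest fill and the mask is re-binarized at
  0.5. The random scheme (the training default) draws rotation from
  ±0.2·180°, shifts of ±5% of the image size, and zooms of ±5%, all with
  nearest fill — the dimensionless-factor convention of common augmentation
  layers, with shift/zoom read as fractions of image size.

## Metrics and area

DSC and IoU score 1.0 when both masks are empty (a correct all-negative
prediction is not penalized; the set formulas are 0/0 there). Metrics are
computed per slice and averaged by default; a pixel-pooled mode accumulates
counts over the dataset first. Trial summaries use the sample (n−1)
standard deviation, the appropriate choice for small trial counts, with an
exact-zero SD when all trials are identical.

Area quantification is deliberately literal: N_P counts every 1-pixel (no
connected-component filtering by default; a minimum-blob-size filter exists
but is off), P_A = S_x·S_y supports anisotropic spacing, and
Area = P_A × N_P exactly — the invariants (quadratic scaling in spacing,
additivity over disjoint masks) hold to float associativity. Spacing
sources are tried in the order DICOM tag (0028,0030) → sidecar CSV → CLI
flag, and it is an error if none is available.

## Phantom generator

Each slice is a dark elliptical "brain" (intensity 0.25 on a 0.02
background) covering most of the frame, textured with σ=3 px Gaussian-
filtered noise scaled to `background_texture_sigma`, plus — with probability
`tumor_probability` — one rotated hyperintense ellipse with semi-axes drawn
from `tumor_semi_axes_range`. The lesion's intensity profile is
`contrast·(0.5 + 0.5·exp(−3r²))` in normalized elliptical radius r, so even
boundary pixels sit at least half the contrast above the local tissue;
additive Gaussian noise (`noise_sigma`) and clipping to [0,1] come last, and
the grayscale slice is replicated to 3 channels. The mask is the exact set
of pixels whose centers satisfy the ellipse inequality — pixel counts are
exact integers, recorded in the sidecar metadata.

Default study conditions: 128×128 px, 1.0 mm isotropic spacing (a typical
FLAIR in-plane order of magnitude; the spacing is metadata, not physics),
70% lesion prevalence, semi-axes 6–20 px, contrast 0.35, texture 0.06,
noise 0.02. The generator emulates the *contract* of a FLAIR lesion dataset
(hyperintense compact lesion, binary expert mask, spacing metadata), not MRI
physics: no bias fields, partial-volume effects, Rician noise, 3-D anatomy,
or multi-focal disease. Passing tests therefore demonstrate that the
pipeline is correct and trainable, not that the shipped defaults reach any
particular accuracy on clinical data.

## Desk-scale problem sizes

Everything in the test suite and acceptance script is sized for minutes on
one CPU: census checks build the full 256×256 models (construction only);
forward-pass checks run at 64×64 with a 0.25 width multiplier; the training
smoke uses 20 all-lesion 32×32 phantoms (semi-axes 4–9 px, contrast 0.4,
noise 0.03), a width-multiplier-0.125 model with dropout 0 (an overfitting
probe wants no regularization), and at most 200 full-batch Adamax steps at
the protocol settings, reaching mean training Dice ≥ 0.98. The same run
backs the README example.

## Known limitations

* 2-D only: per-slice areas, no volumes; one lesion per slice is the
  phantom assumption, though the area pipeline counts all positive pixels.
* The NumPy engine is single-threaded NumPy/BLAS; it is built for
  correctness and desk-scale runs, not for training full-resolution models.
* Pretrained VGG19 weights are not bundled; the encoder initializes
  randomly (a weights file can be loaded through the checkpoint API).
* Tumor grading, survival modeling, and multi-class lesion typing are out
  of scope.
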