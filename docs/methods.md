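# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic phantoms do and do not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Architecture

The network is a U-shaped hybrid: a four-stage transformer encoder with
convolutional token handling, and a convolutional decoder specialised for
irregular boundaries.

**Stem.** 7×7×7 convolution, stride 2, padding 3, followed by layer
normalisation over channels and GELU. The wide strided kernel gives every
token a local receptive field before any attention runs; this local
inductive bias is what permits omitting positional encodings altogether
(asserted in the tests as exact permutation-equivariance of a CT block at
reduction 1).

**Stage layout.** The stem output (1/2 resolution) feeds stage 1 directly;
stride-2 non-overlapping 2×2×2 convolutional patch embeddings (with layer
norm) sit between stages. Stage outputs therefore live at 1/2, 1/4, 1/8,
1/16 resolution, with depths (2, 2, 2, 4), heads (2, 4, 8, 16) and
key/value reduction rates (8, 4, 2, 1). Because stage_scale × reduction =
16 throughout, keys and values have one common spatial size — 1/16 of the
input per axis (8³ for a 128³ crop) — at every stage.

**Convolutional projection.** Queries are the (normalised) tokens
themselves. Keys and values are produced by reshaping tokens to the 3D
grid, applying a depth-wise convolution of kernel k and stride k, and
flattening; K and V use two separate depth-wise convolutions (whether they
share one is not determined by the architecture description; separate ones
are the more general reading and cost almost nothing). All of Q, K, V then
pass through learned pointwise projections before head splitting —
required for the multi-head form to mix channel subspaces. Head splitting
partitions channels into n heads with d_k = C/n; the alternative reading
in which the reduced K/V sequence is literally repeated per head would
make all heads identical and is not implemented.

**Transformer block.** Pre-norm residual layout, unchanged from the
vanilla design: x + MHSA(LN(x)), then + MLP(LN(·)) with expansion ratio 4
and GELU. No positional encoding anywhere.

**Direction-wise convolution block.** Six sub-paths, one per permutation
of (X, Y, Z); each applies three depth-wise uni-directional convolutions
(kernels a×1×1, 1×a×1, 1×1×a, same padding) in its axis order. Kernel
length a = 7 by default (configurable): long thin kernels are the point of
the directional decomposition — a 7³ dense kernel's reach at a fraction of
its cost. Each sub-path maps C→C; the 6C concatenation is projected back
to C by a pointwise convolution (avoiding divisibility-by-6 constraints on
widths), layer-normalised, added to the input, and passed through GELU
(activation after the identity mapping).

**Decoder path.** Bottleneck (1/16) → ×2 transposed convolution (kernel 2,
stride 2; learnable, the standard choice in 3D U-shapes) → concatenation
with the skip → residual fusion block (3³ conv + LN + GELU, 3³ conv + LN,
pointwise-projected shortcut, GELU) → DW-Conv block. Three such steps reach
1/2; a final ×2 transposed convolution reaches the original scale — there
is deliberately no full-resolution encoder skip, which would hold
original-size features through the whole network at prohibitive memory —
followed by one more DW-Conv block at a reduced head width and the 1×1×1
softmax head. Exactly four DW-Conv blocks run, at scales 8, 4, 2, 1. A
`block_type: residual` configuration swaps every DW-Conv block for a plain
residual block with identical interfaces (the ablation topology), asserted
structurally in the tests.

**Output head.** Softmax over C₂ = 4 mutually exclusive classes
(background + labels 1/2/4); the nested WT/TC/ET regions are derived from
the argmax labels afterwards. The alternative 3-channel reading (directly
predicting the overlapping regions) conflicts with a softmax head and a
one-hot target in the loss; it remains reachable by configuring
`n_classes: 3` with region-encoded targets but is not the default.

## Loss and metrics

L(G, P) = [1 − (2/C) Σ_c (Σ_i G_ic P_ic)/(Σ_i G²_ic + Σ_i P²_ic + ε)] −
(1/I) Σ_i Σ_c G_ic log P_ic, with ε = 1e-5 smoothing the dice denominator
and probabilities clamped at 1e-7 inside the log. At a perfect one-hot
prediction each dice fraction is 1/2 and the loss is 0 (to O(ε)). A class
absent from both target and prediction contributes a zero fraction under
the literal 2/C scaling (`include_empty_classes: true`, the default);
setting it false averages over present classes only, restoring exact zero
at perfection with missing classes. Dice on empty-vs-empty masks is
defined as 1.0 (vacuously perfect) and documented at the function.

## Data pipeline

Intensity normalisation maps each channel through its 5th/95th foreground
percentiles to [0, 1] with clipping; "foreground" means strictly nonzero
voxels, the natural reading for skull-stripped images whose background is
exactly zero. Percentiles are per channel (modalities have unrelated
intensity scales). Cropping mixes uniform random origins with label-guided
crops centred on a uniformly drawn tumour voxel (origin clipped to
bounds), 1:1 by default. Augmentation applies intensity scale/shift
(±10%, always), Gaussian noise (sd 0.05, p = 0.15), per-axis flips
(p = 0.5) and per-plane 90° rotations (p = 0.5) — rotations are restricted
to quarter turns so labels are permuted, never interpolated. Axis order is
(channel, X, Y, Z), coordinates 0-based, NIfTI-1 on disk with channels
stored last.

## Sliding-window inference

Stride per axis = max(1, round(roi·(1−overlap))); the final window per
axis is clamped flush to the boundary, guaranteeing full coverage (a
hypothesis property test). The Gaussian importance map is separable with
σ = 0.125·roi per axis, peak-normalised to 1 and floored at 1e-3 of the
peak so no voxel receives zero weight. Blending operates in probability
space (after softmax) — logit-space blending is ill-defined across
overlapping windows whose logits are shifted independently — and
normalises by the accumulated weight, so outputs remain on the per-voxel
simplex regardless of weighting mode. Volumes smaller than the ROI are
symmetrically zero-padded and cropped back. The resize-twice baseline uses
trilinear interpolation in both directions with renormalisation.

## Numerical core

The network runs on an in-package reverse-mode autodiff engine over numpy:
grouped strided 3D convolution via im2col with a scatter-add adjoint,
non-overlapping transposed convolution (kernel = stride), batched matmul,
layer norm, softmax and exact-erf GELU as primitives with hand-written
adjoints, everything else composed. All primitive adjoints are verified
against central finite differences in the test suite. Default dtype is
float32; float64 is available via `ModelConfig.dtype` and used where tests
assert bit-identical determinism. Initialisation: truncated normal
(σ = 0.02, clipped at 2σ) for linear projections, fan-in-scaled truncated
normal for convolutions, ones/zeros for norms; every model is fully
reproducible from its integer seed. AdamW uses β = (0.9, 0.999),
eps = 1e-8, decoupled weight decay 1e-5, with global-norm gradient
clipping at 1.0 — protective in the batch-size-1 regime. The cosine
schedule anneals from the initial lr toward 0 across the configured
epochs.

## Flop accounting

Convention: one multiply-add = 2 flops; convolution and matmul terms only
(norms, activations, softmax, bias adds ignored). Since the convention is
itself a choice, reports carry both the 2-flop total and the raw
multiply-add total. The analytic counter walks the configuration; an
independent instrumented counter accumulates the same primitive classes
from actual runtime shapes during a forward pass, and the two must agree
within 5% (they agree exactly on the shipped architecture). Stage widths
are the one free capacity parameter; they were calibrated once against the
~640 GFlops budget for a 4×128³ input by a grid over stem width
{48, 64, 96} with doubling widths (386.8 / 633.8 / 1304.9 GFlops), fixing
stem 64. This calibration is part of the shipped configuration, not a
tunable.

## Synthetic phantoms

A phantom is a brain ellipsoid (healthy tissue, nonzero intensity, label
0) on an exactly-zero background, containing ellipsoidal lesions with
concentric cores labelled edema 2 / necrotic 1 / enhancing 4, nested by
construction (TC at 0.65 and ET at 0.40 of the WT radii by default). Each
channel assigns each tissue a distinct mean (levels 0.2/0.4/0.6/0.8,
cyclically permuted per channel, differences > 3× the noise sd of 0.05),
so multi-channel input is informative. The default lesion (radius ~10 in
128³) occupies ≈0.2% of the volume — the class-imbalance regime the
cropping strategy targets. An optional smooth warp field deforms the
ellipsoids for harder tests while preserving nesting.

What phantoms do *not* emulate: MRI physics (bias fields, partial volume,
acquisition noise structure), anatomical context, inter-site intensity
variation, or realistic lesion morphology. Tissues are separable by
per-voxel intensity alone, so a passing phantom pipeline demonstrates that
the machinery (shapes, gradients, sampling, blending, bookkeeping) is
correct — not that the architecture reaches clinical accuracy; that claim
requires real data and full-scale training, which are out of scope here.

## Desk-scale problem sizes

Tests and examples run a narrow model (stem 8, widths 8/16/32/64, head
width 8) on 16³–48³ phantoms with 16³–32³ patches — chosen so the whole
suite, including two short training runs, completes in minutes on one CPU
core. At these widths the published initial learning rate (1e-4, the
TrainConfig default) is needlessly conservative; desk-scale runs use 3e-3,
which overfits one 32³ phantom to WT Dice ≥ 0.99 within 300 steps and
reaches ~0.87 held-out WT Dice after 50 epochs on eight 48³ phantoms. The
80/20 case split, crop mix, augmentation and inference settings are the
full-scale ones.

## Known limitations

- CPU-only and unbatched; a full-width 128³ forward pass is supported but
  slow, and stage-1 attention at that size allocates a large L×L_kv
  matrix (~0.5 GB/head in float32). Training the published width on real
  data is out of scope.
- The transposed-convolution primitive requires kernel = stride (the ×2
  case used by the decoder).
- `plan_windows` requires roi ≤ volume; callers pad first (the inference
  wrapper does this automatically).
- Fine-tuning keeps all four encoder stages as the transferred "deep
  layers"; finer-grained layer selection is not implemented.
- Five-fold cross-validation is not built in; the split helper exposes a
  seeded single split (80/20 by default).
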