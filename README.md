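# tctnet

A hybrid Transformer–CNN network for 3D tumour segmentation in multi-modal
MRI, implemented as a pure scientific-Python library (numpy/scipy, with a
small built-in reverse-mode autodiff engine) plus a thin `tctnet` command
line. The package covers the full workflow: BraTS-style data handling,
patch-based training against class imbalance, and Gaussian-weighted
sliding-window inference — all exercisable end-to-end on bundled synthetic
phantoms, with no external data or GPU.

## The model

**Encoder.** A Stem block (7×7×7 convolution, stride 2, padding 3, layer
norm, GELU) halves the input and injects local inductive bias — which is
what lets the architecture drop positional encoding entirely. Four stages
of *Convolution Transformer* blocks follow, separated by stride-2
convolutional patch embeddings, producing a feature pyramid at 1/2, 1/4,
1/8, 1/16 resolution with widths (64, 128, 256, 512).

Each CT block is a pre-norm transformer block whose keys and values come
from a *convolutional projection*: tokens x′ ∈ R^{L×C} are reshaped to the
3D grid, passed through a depth-wise convolution of stride k (the per-stage
reduction rate), and flattened back,

    Q = x′,   K′ = Flatten(DWConv3D(Reshape3D(x′))),   V′ likewise,

shrinking the key/value sequence by k³ before the standard scaled
dot-product attention Softmax(QK′ᵀ/√d_k)V′. With reduction rates
(8, 4, 2, 1) against stage scales (2, 4, 8, 16), K/V sit at 1/16 of the
input on every stage, so attention cost stays flat across the hierarchy.
Stage depths are (2, 2, 2, 4) and head counts (2, 4, 8, 16).

**Decoder.** From the 1/16 bottleneck, each step upsamples ×2 (transposed
convolution), fuses with the skip feature through a residual block, and
refines with a *3D Direction-Wise Convolution* block: six sub-paths, one
per permutation of the X, Y, Z axes, each applying depth-wise
uni-directional kernels (a×1×1, 1×a×1, 1×1×a; a = 7) in its axis order;
sub-path outputs are concatenated, projected back, layer-normalised, added
residually, and passed through GELU. Exactly four DW-Conv blocks run — at
scales 8, 4, 2 and the original scale — before a 1×1×1 softmax head.

**Loss.** Soft dice + cross-entropy over C exclusive classes and I voxels:

    L(G, P) = [1 − (2/C) Σ_c (Σ_i G_ic P_ic)/(Σ_i G²_ic + Σ_i P²_ic + ε)]
              − (1/I) Σ_i Σ_c G_ic log P_ic

Evaluation reports the Dice Similarity Coefficient 2|A∩B|/(|A|+|B|) on the
nested BraTS regions WT ⊇ TC ⊇ ET derived from labels {1, 2, 4}.

**Training and inference.** Patches (128³ at full scale) are sampled 1:1
from random and label-guided crops — the latter centred on tumour voxels to
fight the ~99.5% background dominance — augmented (flips, 90° rotations,
intensity scale/shift/noise), and optimised with AdamW under a
cosine-annealed learning rate (initial 1e-4, batch size 1). Full volumes
are segmented by sliding-window inference at overlap 0.5 with Gaussian
importance weighting (σ = 0.125·ROI per axis), blending overlapping window
probabilities so centre voxels dominate.

## Worked example

```python
import numpy as np
from tctnet import (ModelConfig, PhantomSpec, TrainConfig, dice_score,
                    generate_phantom, normalise_intensity, predict_case,
                    regions_from_labels)
from tctnet.training import Case, run_training, split_cases

cases = []
for i in range(10):
    vol, lab = generate_phantom(PhantomSpec(shape=(48, 48, 48),
                                            lesion_radius_range=(6., 9.),
                                            seed=100 + i))
    cases.append(Case(f"c{i}", normalise_intensity(vol), lab))
train_cases, val_cases = split_cases(cases, val_fraction=0.2, seed=0)

cfg = TrainConfig(epochs=50, patch_size=(32, 32, 32), lr=3e-3, seed=0,
                  checkpoint_path="")
result = run_training(cfg, ModelConfig.tiny(seed=0), cases=train_cases)
for case in val_cases:
    pred = predict_case(result.model, case.volume, (32, 32, 32))
    wt = dice_score(regions_from_labels(pred).WT,
                    regions_from_labels(case.labels.labels).WT)
    print(case.name, f"WT dice {wt:.3f}")
```

On one CPU this trains a desk-scale model (widths 8/16/32/64) in about
three minutes and prints held-out whole-tumour Dice near

```
c4 WT dice 0.880
c6 WT dice 0.865
```

meaning the learned segmentation overlaps ~87% of the true tumour volume on
phantoms never seen in training. The `examples/` directory holds one short
script per capability (flop budget, phantom generation, crop-ratio
experiment, sliding-window mechanics, training); each prints what it
computes and what the numbers mean. The same workflow is available from the
shell:

```
tctnet make-phantoms --n 10 --shape 96x96x96 --out data/
tctnet train --data data/ --tiny --epochs 50 --patch-size 32x32x32 --ckpt m.npz
tctnet infer --ckpt m.npz --in data/case000_image.nii.gz --out pred.nii.gz --roi 32x32x32
tctnet evaluate --pred preds/ --gt labels/
tctnet flops --shape 4x128x128x128
```

## Compute budget and width calibration

The architecture leaves the stage widths open; they are the one capacity
knob. The shipped defaults were fixed by a one-time calibration against the
~640 GFlops forward-pass budget for a 4-channel 128³ input: a grid over
stem width ∈ {48, 64, 96} with doubling stage widths gives 386.8, 633.8 and
1304.9 GFlops respectively (multiply-add = 2 flops, conv + attention
terms), so stem 64 / widths (64, 128, 256, 512) — the config minimising
|total − 640| — is the default. `tctnet flops` prints the per-layer
breakdown under both flop conventions, and the analytic counter is
cross-checked in the tests against an instrumented forward pass that counts
the same primitives from runtime array shapes.

## Scope

Desk-scale by design: the full-width model trains on multi-GPU hardware
with real BraTS/MSD data, neither of which this package bundles; phantom
experiments validate mechanisms, not clinical performance. See
`docs/methods.md` for model assumptions, parameter defaults, numerical
choices, and known limitations.
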