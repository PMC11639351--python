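"""Combined soft-dice + cross-entropy loss, Dice score, nested tumour regions.

The training loss couples a voxel-mean cross-entropy with a soft dice term
averaged over classes:

    L(G, P) = [1 - (2/C) * sum_c (sum_i G_ic P_ic) / (sum_i G_ic^2 + sum_i P_ic^2 + eps)]
              - (1/I) * sum_i sum_c G_ic log P_ic

with I voxels, C classes, one-hot ground truth G and probabilities P. At a
perfect one-hot prediction each class's dice fraction is 1/2 (numerator
equals half the denominator), so the bracket vanishes and L = 0.

Evaluation uses the Dice Similarity Coefficient on the three nested tumour
regions of the BraTS labelling convention: whole tumour WT = {1, 2, 4},
tumour core TC = {1, 4}, enhancing tumour ET = {4} (label 1 = necrotic /
non-enhancing core, 2 = peritumoral edema, 4 = enhancing tumour), with
ET <= TC <= WT by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ShapeError, ValidationError

__all__ = [
    "soft_dice_ce_loss",
    "dice_score",
    "regions_from_labels",
    "one_hot",
    "RegionMasks",
    "REGION_LABELS",
    "VALID_LABELS",
]

VALID_LABELS = frozenset({0, 1, 2, 4})
REGION_LABELS: dict[str, tuple[int, ...]] = {
    "WT": (1, 2, 4),
    "TC": (1, 4),
    "ET": (4,),
}
LOG_CLAMP = 1e-7
DICE_EPS = 1e-5


@dataclass
class RegionMasks:
    """Boolean masks of the nested tumour regions (ET <= TC <= WT)."""

    WT: np.ndarray
    TC: np.ndarray
    ET: np.ndarray

    def __getitem__(self, region: str) -> np.ndarray:
        return getattr(self, region)

    def items(self):
        return (("WT", self.WT), ("TC", self.TC), ("ET", self.ET))


def one_hot(labels: np.ndarray, class_values: tuple[int, ...] = (0, 1, 2, 4),
            dtype=np.float32) -> np.ndarray:
    """Encode an integer label grid as a C x spatial one-hot array."""
    labels = np.asarray(labels)
    unknown = set(np.unique(labels)) - set(class_values)
    if unknown:
        raise ValidationError(f"unknown label values {sorted(unknown)}")
    return np.stack([(labels == v) for v in class_values]).astype(dtype)


def soft_dice_ce_loss(P: Tensor | np.ndarray, G: np.ndarray,
                      eps: float = DICE_EPS,
                      include_empty_classes: bool = True) -> Tensor:
    """Soft dice + cross-entropy loss over a C x spatial probability grid.

    `P` holds per-voxel class probabilities (simplex per voxel); `G` the
    one-hot ground truth of the same shape. When `include_empty_classes` is
    true, a class absent from both G and P contributes a zero dice fraction
    to the 2/C-scaled sum (the literal formula); when false, absent classes
    are dropped and the remaining fractions averaged, so a perfect
    prediction scores exactly zero even with missing classes.
    """
    if not isinstance(P, Tensor):
        P = Tensor(np.asarray(P))
    G = np.asarray(G, dtype=P.data.dtype)
    if P.shape != G.shape:
        raise ShapeError(f"P shape {P.shape} != G shape {G.shape}")
    if P.data.min() < -1e-6 or P.data.max() > 1 + 1e-6:
        raise ValidationError("probabilities outside [0, 1]")
    c = P.shape[0]
    n_vox = int(np.prod(P.shape[1:]))
    p = P.reshape(c, n_vox)
    g = G.reshape(c, n_vox)

    ce = -(Tensor(g) * ad.log(ad.maximum(p, LOG_CLAMP))).sum() * (1.0 / n_vox)

    inter = (p * g).sum(axis=1)                      # (C,)
    denom = (p * p).sum(axis=1) + (g * g).sum(axis=1) + eps
    fractions = inter / denom
    if include_empty_classes:
        dice_term = fractions.sum() * (2.0 / c)
    else:
        present = (g.sum(axis=1) > 0) | (p.data.sum(axis=1) > eps)
        n_present = max(int(present.sum()), 1)
        dice_term = (fractions * present.astype(p.dtype)).sum() * (2.0 / n_present)
    return (1.0 - dice_term) + ce


def dice_score(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Dice Similarity Coefficient 2|A&B| / (|A| + |B|).

    Returns 1.0 when both masks are empty (the prediction is vacuously
    perfect); symmetric in its arguments.
    """
    pred_mask = np.asarray(pred_mask, dtype=bool)
    gt_mask = np.asarray(gt_mask, dtype=bool)
    if pred_mask.shape != gt_mask.shape:
        raise ShapeError(f"mask shapes differ: {pred_mask.shape} vs {gt_mask.shape}")
    a = int(pred_mask.sum())
    b = int(gt_mask.sum())
    if a + b == 0:
        return 1.0
    return 2.0 * int((pred_mask & gt_mask).sum()) / (a + b)


def regions_from_labels(labels: np.ndarray) -> RegionMasks:
    """Derive the nested WT/TC/ET masks from an exclusive-label grid."""
    labels = np.asarray(labels)
    unknown = set(np.unique(labels)) - VALID_LABELS
    if unknown:
        raise ValidationError(
            f"unknown label values {sorted(int(v) for v in unknown)}; "
            f"expected a subset of {sorted(VALID_LABELS)}"
        )
    return RegionMasks(
        WT=np.isin(labels, REGION_LABELS["WT"]),
        TC=np.isin(labels, REGION_LABELS["TC"]),
        ET=np.isin(labels, REGION_LABELS["ET"]),
    )
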