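"""Synthetic BraTS-like phantoms.

A phantom emulates the *structure* of skull-stripped multi-modal brain MRI
with nested tumour sub-regions, not MRI physics: a large "brain" ellipsoid
of healthy tissue (nonzero intensity, label 0) on a zero background, and
one or more lesions, each an axis-aligned ellipsoid with concentric cores
labelled in the BraTS convention — edema shell (2), necrotic /
non-enhancing ring (1), enhancing core (4) — so the derived nested regions
satisfy ET <= TC <= WT by construction. Each channel assigns a distinct
mean intensity to every tissue (channels are informative), plus additive
Gaussian noise. Background dominates: the default single r~10 lesion in a
128^3 grid occupies ~0.2% of the volume, matching the extreme class
imbalance that label-guided cropping exists to fight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data import LabelMap, Volume, save_prediction
from .errors import ValidationError
from .losses import regions_from_labels

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "TISSUE_LEVELS"]

# per-channel intensity level index for each tissue; actual mean is
# 0.2 + 0.2 * level, so within any channel tissue means differ by >= 0.2
TISSUES = ("brain", "necrotic", "edema", "enhancing")
TISSUE_LABEL = {"brain": 0, "necrotic": 1, "edema": 2, "enhancing": 4}


def TISSUE_LEVELS(channel: int, tissue_index: int) -> float:
    return 0.2 + 0.2 * ((channel + tissue_index) % 4)


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (128, 128, 128)
    n_channels: int = 4
    n_lesions: int = 1
    lesion_radius_range: tuple[float, float] = (8.0, 12.0)
    nesting_fractions: tuple[float, float] = (0.65, 0.4)  # (f_TC, f_ET) of WT radius
    noise_sd: float = 0.05
    seed: int = 0
    warp: bool = False  # smooth random deformation of the lesion ellipsoids

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        lo, hi = self.lesion_radius_range
        if lo < 1:
            raise ValidationError("lesion radii must be >= 1 voxel")
        f_tc, f_et = self.nesting_fractions
        if not (0 < f_et <= f_tc <= 1):
            raise ValidationError(
                f"nesting fractions must satisfy 0 < f_ET <= f_TC <= 1, got "
                f"({f_tc}, {f_et})"
            )


def _ellipsoid_mask(shape, centre, radii, warp_field=None) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r2 = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, centre, radii):
        r2 += ((g - c) / r) ** 2
    if warp_field is not None:
        r2 += warp_field
    return r2 <= 1.0


def _smooth_noise(shape, rng, amplitude: float = 0.25) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 8)
    peak = np.abs(field).max()
    return amplitude * field / (peak if peak > 0 else 1.0)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Deterministically build one phantom volume + label map from `spec`."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    labels = np.zeros(shape, dtype=np.int16)

    # healthy brain ellipsoid centred in the grid
    brain_radii = [0.42 * s for s in shape]
    brain_centre = [(s - 1) / 2.0 for s in shape]
    brain = _ellipsoid_mask(shape, brain_centre, brain_radii)

    f_tc, f_et = spec.nesting_fractions
    lo, hi = spec.lesion_radius_range
    warp_field = _smooth_noise(shape, rng) if spec.warp else None
    for _ in range(spec.n_lesions):
        radii = rng.uniform(lo, hi, size=3)
        rmax = float(radii.max())
        margin = rmax + 2
        if any(2 * margin >= s for s in shape):
            raise ValidationError(
                f"lesion radius {rmax:.1f} cannot fit inside shape {shape}"
            )
        # sample a centre inside the brain, away from the boundary
        for _attempt in range(200):
            centre = [rng.uniform(margin, s - 1 - margin) for s in shape]
            if brain[tuple(int(round(c)) for c in centre)]:
                break
        else:
            raise ValidationError("could not place a lesion inside the brain")
        wt = _ellipsoid_mask(shape, centre, radii, warp_field)
        tc = _ellipsoid_mask(shape, centre, radii * f_tc, warp_field)
        et = _ellipsoid_mask(shape, centre, radii * f_et, warp_field)
        labels[wt] = TISSUE_LABEL["edema"]
        labels[tc] = TISSUE_LABEL["necrotic"]
        labels[et] = TISSUE_LABEL["enhancing"]

    tissue_index = np.zeros(shape, dtype=np.int8)  # 0 brain
    tissue_index[labels == 1] = 1
    tissue_index[labels == 2] = 2
    tissue_index[labels == 4] = 3

    inside = brain | (labels > 0)
    image = np.zeros((spec.n_channels,) + shape, dtype=np.float32)
    for c in range(spec.n_channels):
        means = np.array([TISSUE_LEVELS(c, t) for t in range(4)], dtype=np.float32)
        chan = means[tissue_index]
        chan += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        image[c] = np.where(inside, np.clip(chan, 1e-3, None), 0.0)

    vol = Volume(image)
    lab = LabelMap(labels)
    masks = regions_from_labels(labels)  # construction guarantees the nesting
    assert not (masks.ET & ~masks.TC).any() and not (masks.TC & ~masks.WT).any()
    return vol, lab


def generate_dataset(n_cases: int, spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write n_cases image/label NIfTI pairs and a JSON manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = []
    for i in range(n_cases):
        case_spec = PhantomSpec(**{**asdict(spec), "seed": spec.seed + i})
        vol, lab = generate_phantom(case_spec)
        name = f"case{i:03d}"
        img_path = out_dir / f"{name}_image.nii.gz"
        lab_path = out_dir / f"{name}_label.nii.gz"
        save_prediction(img_path, vol.intensities, vol.affine, vol.spacing)
        save_prediction(lab_path, lab.labels, lab.affine)
        masks = regions_from_labels(lab.labels)
        cases.append({
            "name": name,
            "image": img_path.name,
            "label": lab_path.name,
            "seed": case_spec.seed,
            "wt_voxels": int(masks.WT.sum()),
            "tc_voxels": int(masks.TC.sum()),
            "et_voxels": int(masks.ET.sum()),
        })
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({
        "spec": {**asdict(spec), "shape": list(spec.shape),
                 "lesion_radius_range": list(spec.lesion_radius_range),
                 "nesting_fractions": list(spec.nesting_fractions)},
        "n_cases": n_cases,
        "cases": cases,
    }, indent=2))
    return manifest
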