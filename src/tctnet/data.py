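"""Data pipeline: NIfTI I/O, intensity normalisation, cropping, augmentation.

Conventions: axis order is (channel, X, Y, Z); coordinates are 0-based voxel
indices; default voxel spacing is 1.0 x 1.0 x 1.0 mm^3 (skull-stripped,
co-registered multi-modal MRI, BraTS-style). "Foreground" for percentile
normalisation means strictly nonzero voxels — skull-stripped images are
exactly zero outside the brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .config import AugmentConfig
from .errors import ShapeError, ValidationError
from .losses import regions_from_labels, REGION_LABELS

__all__ = [
    "Volume",
    "LabelMap",
    "PatchPair",
    "normalise_intensity",
    "random_crop",
    "label_guided_crop",
    "augment",
    "tumour_ratio",
    "load_volume",
    "load_labels",
    "save_prediction",
]


@dataclass
class Volume:
    """A C1 x X x Y x Z multi-channel intensity grid with geometry."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim == 3:
            self.intensities = self.intensities[None]
        if self.intensities.ndim != 4:
            raise ShapeError(
                f"Volume expects C x X x Y x Z, got shape {self.intensities.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]


@dataclass
class LabelMap:
    """Integer X x Y x Z grid of mutually exclusive tissue labels."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ShapeError(f"LabelMap expects X x Y x Z, got {self.labels.shape}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class PatchPair:
    """An image patch, its aligned label patch, and the crop origin."""

    image: np.ndarray   # C1 x px x py x pz
    labels: np.ndarray  # px x py x pz
    origin: tuple[int, int, int]


# ---------------------------------------------------------------------------
# normalisation


def normalise_intensity(vol: Volume) -> Volume:
    """Map each channel to [0, 1] via the 5th/95th foreground percentiles.

    Per channel: with p5, p95 the percentiles of the strictly nonzero
    voxels, every voxel maps through clip((x - p5) / (p95 - p5), 0, 1) —
    background included, so zero background stays at or below zero and is
    clipped to 0.
    """
    out = np.empty_like(vol.intensities, dtype=np.float32)
    for c in range(vol.n_channels):
        channel = vol.intensities[c]
        fg = channel[channel != 0]
        if fg.size == 0:
            raise ValidationError(f"channel {c} is all zero; cannot normalise")
        p5, p95 = np.percentile(fg, [5, 95])
        if p95 <= p5:
            raise ValidationError(
                f"channel {c} has a degenerate foreground range (p5=p95={p5})"
            )
        out[c] = np.clip((channel - p5) / (p95 - p5), 0.0, 1.0)
    return Volume(out, vol.spacing, vol.affine)


# ---------------------------------------------------------------------------
# cropping


def _check_patch_size(size, shape) -> tuple[int, int, int]:
    size = tuple(int(s) for s in size)
    if any(p > s for p, s in zip(size, shape)):
        raise ShapeError(
            f"patch size {size} exceeds volume shape {tuple(shape)}; "
            f"pad the volume before cropping"
        )
    return size


def _extract(vol: Volume, labels: LabelMap, origin, size) -> PatchPair:
    x, y, z = origin
    px, py, pz = size
    return PatchPair(
        image=vol.intensities[:, x:x + px, y:y + py, z:z + pz].copy(),
        labels=labels.labels[x:x + px, y:y + py, z:z + pz].copy(),
        origin=(int(x), int(y), int(z)),
    )


def random_crop(vol: Volume, labels: LabelMap, size, rng: np.random.Generator
                ) -> PatchPair:
    """Crop with origin uniform over all in-bounds positions."""
    size = _check_patch_size(size, vol.spatial_shape)
    origin = tuple(
        int(rng.integers(0, s - p + 1)) for s, p in zip(vol.spatial_shape, size)
    )
    return _extract(vol, labels, origin, size)


def label_guided_crop(vol: Volume, labels: LabelMap, size, rng: np.random.Generator
                      ) -> PatchPair:
    """Crop centred on a uniformly chosen foreground (tumour) voxel.

    The origin is clipped to bounds, so the chosen voxel is always inside
    the patch and the patch always contains at least one foreground voxel.
    """
    size = _check_patch_size(size, vol.spatial_shape)
    fg = np.argwhere(labels.labels > 0)
    if fg.size == 0:
        raise ValidationError(
            "labels contain no foreground voxel; fall back to random_crop"
        )
    centre = fg[int(rng.integers(0, len(fg)))]
    origin = tuple(
        int(np.clip(c - p // 2, 0, s - p))
        for c, p, s in zip(centre, size, vol.spatial_shape)
    )
    return _extract(vol, labels, origin, size)


# ---------------------------------------------------------------------------
# augmentation

_PLANES = ((0, 1), (0, 2), (1, 2))  # the three orthogonal rotation planes


def augment(pair: PatchPair, rng: np.random.Generator,
            cfg: AugmentConfig | None = None) -> PatchPair:
    """Random intensity and spatial augmentation of a patch pair.

    Intensity ops (scale, shift, additive Gaussian noise) touch the image
    only. Spatial ops (axis flips and 90-degree rotations in the three
    orthogonal planes) are permutations of the voxel grid applied jointly
    to image and labels, so label values are never interpolated.
    """
    cfg = cfg if cfg is not None else AugmentConfig()
    img = pair.image.astype(np.float32, copy=True)
    lab = pair.labels.copy()

    if rng.random() < cfg.prob_scale:
        img *= 1.0 + rng.uniform(-cfg.scale_range, cfg.scale_range)
    if rng.random() < cfg.prob_shift:
        img += rng.uniform(-cfg.shift_range, cfg.shift_range)
    if rng.random() < cfg.prob_noise:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape).astype(np.float32)

    for axis in range(3):
        if rng.random() < cfg.prob_flip:
            img = np.flip(img, axis=axis + 1)
            lab = np.flip(lab, axis=axis)
    for ax1, ax2 in _PLANES:
        if rng.random() < cfg.prob_rot90:
            k = int(rng.integers(1, 4))
            img = np.rot90(img, k=k, axes=(ax1 + 1, ax2 + 1))
            lab = np.rot90(lab, k=k, axes=(ax1, ax2))
    return PatchPair(np.ascontiguousarray(img), np.ascontiguousarray(lab), pair.origin)


def tumour_ratio(labels: np.ndarray | LabelMap, region: str = "WT") -> float:
    """Fraction of voxels belonging to a nested tumour region (WT/TC/ET)."""
    arr = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    if region not in REGION_LABELS:
        raise ValidationError(f"unknown region {region!r}; expected WT, TC or ET")
    mask = regions_from_labels(arr)[region]
    return float(mask.sum()) / arr.size


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path: str | Path) -> Volume:
    """Read a 3D (single-channel) or 4D (channel-last) NIfTI-1 image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[None]
    elif data.ndim == 4:
        data = np.moveaxis(data, -1, 0)  # stored X,Y,Z,C -> C,X,Y,Z
    else:
        raise ShapeError(f"{path}: expected 3D or 4D NIfTI, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    return Volume(data, tuple(float(z) for z in zooms), img.affine)


def load_labels(path: str | Path, image_shape: tuple[int, int, int] | None = None
                ) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path}: label map must be 3D, got {data.ndim}D")
    if image_shape is not None and tuple(data.shape) != tuple(image_shape):
        raise ShapeError(
            f"{path}: label shape {data.shape} does not match image {image_shape}"
        )
    return LabelMap(np.rint(data).astype(np.int16), img.affine)


def save_prediction(path: str | Path, labels_or_probs: np.ndarray,
                    affine: np.ndarray | None = None,
                    spacing: tuple[float, float, float] | None = None) -> None:
    """Write a label map (3D int) or probability map (C,X,Y,Z -> X,Y,Z,C)."""
    arr = np.asarray(labels_or_probs)
    if arr.ndim == 4:
        arr = np.moveaxis(arr, 0, -1).astype(np.float32)
    elif arr.ndim == 3:
        arr = arr.astype(np.int16)
    else:
        raise ShapeError(f"expected 3D labels or 4D probabilities, got {arr.ndim}D")
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(arr, affine)
    if spacing is not None:
        img.header.set_zooms(tuple(spacing) + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))
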