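"""Configuration dataclasses and their YAML round-trip.

The published encoder configuration is four stages with depths (2, 2, 2, 4),
attention heads (2, 4, 8, 16) and key/value reduction rates (8, 4, 2, 1).
With the stem at 1/2 resolution and a stride-2 convolutional patch embedding
between stages, feature maps sit at 1/2, 1/4, 1/8, 1/16 of the input, so
stage_scale x reduction = 16 on every stage and keys/values share one
spatial size (input/16 per axis) throughout the encoder.

Stage widths are not pinned by the architecture itself; the defaults below
were calibrated once against the 640-GFlops forward-pass budget for a
4-channel 128x128x128 input (see the analytic counter in
:mod:`tctnet.flops` and the calibration note in the README).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

__all__ = [
    "EncoderConfig",
    "DecoderConfig",
    "AugmentConfig",
    "ModelConfig",
    "TrainConfig",
]


@dataclass
class EncoderConfig:
    stage_depths: tuple[int, ...] = (2, 2, 2, 4)
    stage_heads: tuple[int, ...] = (2, 4, 8, 16)
    stage_reductions: tuple[int, ...] = (8, 4, 2, 1)
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    stem_width: int = 64
    mlp_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for name in ("stage_depths", "stage_heads", "stage_reductions", "stage_widths"):
            setattr(self, name, tuple(int(v) for v in getattr(self, name)))
            if len(getattr(self, name)) != 4:
                raise ValidationError(f"{name} must have exactly 4 entries")
        if any(a >= b for a, b in zip(self.stage_widths, self.stage_widths[1:])):
            raise ValidationError("stage_widths must be strictly increasing")
        for w, n in zip(self.stage_widths, self.stage_heads):
            if w % n:
                raise ValidationError(
                    f"stage width {w} not divisible by head count {n}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("stage_depths", "stage_heads", "stage_reductions", "stage_widths"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        return cls(**d)


@dataclass
class DecoderConfig:
    dw_kernel_length: int = 7          # uni-directional kernel length a (odd)
    upsample_mode: str = "transposed"  # learnable x2 transposed convolution
    n_classes: int = 4                 # background + 3 exclusive tissue labels
    head_width: int = 32               # channel width at the original scale
    block_type: str = "dwconv"         # "dwconv" | "residual" (ablation hook)

    def __post_init__(self):
        if self.dw_kernel_length % 2 == 0 or self.dw_kernel_length < 1:
            raise ValidationError("dw_kernel_length must be odd and positive")
        if self.block_type not in ("dwconv", "residual"):
            raise ValidationError(f"unknown block_type {self.block_type!r}")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")


@dataclass
class AugmentConfig:
    """Per-sample augmentation probabilities and magnitudes.

    Intensity ops touch the image only; spatial ops (axis flips, 90-degree
    rotations in the three orthogonal planes) are applied jointly to image
    and labels, so labels never need interpolation.
    """

    prob_flip: float = 0.5        # per axis
    prob_rot90: float = 0.5       # per orthogonal plane; quarter-turn count uniform 1..3
    prob_scale: float = 1.0       # x -> x * (1 + u), u ~ U(-scale_range, scale_range)
    scale_range: float = 0.1
    prob_shift: float = 1.0       # x -> x + u, u ~ U(-shift_range, shift_range)
    shift_range: float = 0.1
    prob_noise: float = 0.15      # additive Gaussian noise on the image
    noise_sd: float = 0.05

    def __post_init__(self):
        for name in ("prob_flip", "prob_rot90", "prob_scale", "prob_shift", "prob_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(prob_flip=0, prob_rot90=0, prob_scale=0, prob_shift=0, prob_noise=0)


@dataclass
class ModelConfig:
    in_channels: int = 4
    n_classes: int = 4
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValidationError("in_channels must be >= 1")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        self.decoder.n_classes = self.n_classes

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "n_classes": self.n_classes,
            "encoder": self.encoder.to_dict(),
            "decoder": asdict(self.decoder),
            "seed": self.seed,
            "dtype": self.dtype,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "encoder" in d:
            d["encoder"] = EncoderConfig.from_dict(d["encoder"])
        if "decoder" in d:
            d["decoder"] = DecoderConfig(**d["decoder"])
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ModelConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = yaml.safe_load(text)
        if "model" in d:  # allow a combined config file
            d = d["model"]
        return cls.from_dict(d)

    @classmethod
    def tiny(cls, in_channels: int = 4, n_classes: int = 4, seed: int = 0) -> "ModelConfig":
        """A desk-scale configuration (widths 8/16/32/64) for tests and demos."""
        enc = EncoderConfig(stage_widths=(8, 16, 32, 64), stem_width=8,
                            stage_heads=(2, 4, 8, 16), seed=seed)
        dec = DecoderConfig(head_width=8, n_classes=n_classes)
        return cls(in_channels=in_channels, n_classes=n_classes,
                   encoder=enc, decoder=dec, seed=seed)


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 1
    lr: float = 1e-4
    schedule: str = "cosine"
    patch_size: tuple[int, int, int] = (128, 128, 128)
    crop_mix: float = 0.5          # fraction of label-guided crops (1:1 with random)
    seed: int = 0
    val_fraction: float = 0.2      # 80/20 split by case with the fixed seed
    finetune_epochs: int = 200
    weight_decay: float = 1e-5
    grad_clip: float = 1.0
    checkpoint_path: str = "model.npz"
    metrics_path: str | None = None  # JSONL metrics log
    val_every: int = 1

    def __post_init__(self):
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValidationError("lr must be > 0")
        if self.schedule not in ("cosine", "constant"):
            raise ValidationError(f"unknown schedule {self.schedule!r}")
        self.patch_size = tuple(int(v) for v in self.patch_size)
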