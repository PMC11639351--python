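"""Decoder: 3D Direction-Wise Convolution blocks, residual fusion, softmax head.

The decoder walks the feature pyramid from the 1/16-scale bottleneck back to
the original resolution. At each step the coarser map is upsampled x2
(transposed convolution), fused with the skip feature of the current scale
through a residual block, and refined by a 3D Direction-Wise Convolution
(DW-Conv) block; a final x2 upsampling reaches the original scale, where one
more DW-Conv block runs before the 1x1x1 softmax head. That places exactly
four DW-Conv blocks, at scales 8, 4, 2 and 1.

A DW-Conv block decomposes a large 3D kernel into uni-directional (one-axis)
convolutions: six sub-paths, one per permutation of the X, Y, Z axes, each
applying depth-wise kernels a x 1 x 1, 1 x a x 1 and 1 x 1 x a in its axis
order. Sub-path outputs are concatenated, projected back to the input width,
layer-normalised, added to the input, and passed through GELU.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import DecoderConfig
from .encoder import FeatureMap, map_to_tokens, tokens_to_map
from .errors import ContractError, ShapeError, ValidationError
from .nn import Conv3d, ConvTranspose3d, LayerNorm, Module

__all__ = [
    "DWConvBlockConfig",
    "DWConvBlock",
    "PlainResidualBlock",
    "UpsampleFuse",
    "SegmentationHead",
    "Decoder",
    "AXIS_ORDERS",
]

# the 6 permutations of the spatial axes (X, Y, Z) = axes (0, 1, 2)
AXIS_ORDERS: tuple[tuple[int, int, int], ...] = tuple(permutations((0, 1, 2)))


@dataclass
class DWConvBlockConfig:
    channels: int
    kernel_length: int = 7

    def __post_init__(self):
        if self.kernel_length % 2 == 0:
            raise ValidationError("kernel_length must be odd for same padding")


def _directional_kernel(axis: int, a: int) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Kernel shape and padding for a uni-directional conv along `axis`."""
    kernel = [1, 1, 1]
    pad = [0, 0, 0]
    kernel[axis] = a
    pad[axis] = a // 2
    return tuple(kernel), tuple(pad)


class DWConvBlock(Module):
    """6 axis-order sub-paths of depth-wise uni-directional convolutions."""

    def __init__(self, channels: int, rng, kernel_length: int = 7, dtype=np.float32):
        self.cfg = DWConvBlockConfig(channels, kernel_length)
        a = kernel_length
        self.subpaths: list[list[Conv3d]] = []
        for order in AXIS_ORDERS:
            path = []
            for axis in order:
                kernel, pad = _directional_kernel(axis, a)
                path.append(Conv3d(channels, channels, kernel, rng, padding=pad,
                                   groups=channels, dtype=dtype))
            self.subpaths.append(path)
        self.project = Conv3d(6 * channels, channels, 1, rng, dtype=dtype)
        self.norm = LayerNorm(channels, dtype=dtype)

    def named_parameters(self, prefix: str = ""):
        for i, path in enumerate(self.subpaths):
            for j, conv in enumerate(path):
                yield from conv.named_parameters(f"{prefix}subpaths.{i}.{j}.")
        yield from self.project.named_parameters(f"{prefix}project.")
        yield from self.norm.named_parameters(f"{prefix}norm.")

    def forward(self, fm: FeatureMap) -> FeatureMap:
        if fm.channels != self.cfg.channels:
            raise ShapeError(
                f"DWConvBlock expects {self.cfg.channels} channels, got {fm.channels}"
            )
        outs = []
        for path in self.subpaths:
            h = fm.values
            for conv in path:
                h = conv(h)
            outs.append(h)
        fused = self.project(ad.concat(outs, axis=0))
        seq = map_to_tokens(FeatureMap(fused, fm.stage_scale))
        normed = tokens_to_map(
            type(seq)(self.norm(seq.values), seq.spatial_shape), fm.stage_scale
        )
        return FeatureMap(ad.gelu(fm.values + normed.values), fm.stage_scale)


class PlainResidualBlock(Module):
    """Two 3x3x3 convs + norm + GELU with identity shortcut (ablation swap-in)."""

    def __init__(self, channels: int, rng, dtype=np.float32):
        self.channels = channels
        self.conv1 = Conv3d(channels, channels, 3, rng, padding=1, dtype=dtype)
        self.norm1 = LayerNorm(channels, dtype=dtype)
        self.conv2 = Conv3d(channels, channels, 3, rng, padding=1, dtype=dtype)
        self.norm2 = LayerNorm(channels, dtype=dtype)

    def _norm(self, x: Tensor, norm: LayerNorm, scale: int) -> Tensor:
        seq = map_to_tokens(FeatureMap(x, scale))
        return tokens_to_map(type(seq)(norm(seq.values), seq.spatial_shape), scale).values

    def forward(self, fm: FeatureMap) -> FeatureMap:
        if fm.channels != self.channels:
            raise ShapeError(
                f"residual block expects {self.channels} channels, got {fm.channels}"
            )
        h = ad.gelu(self._norm(self.conv1(fm.values), self.norm1, fm.stage_scale))
        h = self._norm(self.conv2(h), self.norm2, fm.stage_scale)
        return FeatureMap(ad.gelu(fm.values + h), fm.stage_scale)


class UpsampleFuse(Module):
    """x2 transposed-conv upsampling + concat with skip + residual fusion."""

    def __init__(self, in_channels: int, skip_channels: int, rng, dtype=np.float32):
        self.up = ConvTranspose3d(in_channels, skip_channels, rng, stride=2, dtype=dtype)
        c = skip_channels
        self.conv1 = Conv3d(2 * c, c, 3, rng, padding=1, dtype=dtype)
        self.norm1 = LayerNorm(c, dtype=dtype)
        self.conv2 = Conv3d(c, c, 3, rng, padding=1, dtype=dtype)
        self.norm2 = LayerNorm(c, dtype=dtype)
        self.shortcut = Conv3d(2 * c, c, 1, rng, dtype=dtype)

    def _norm(self, x: Tensor, norm: LayerNorm, scale: int) -> Tensor:
        seq = map_to_tokens(FeatureMap(x, scale))
        return tokens_to_map(type(seq)(norm(seq.values), seq.spatial_shape), scale).values

    def forward(self, low: FeatureMap, skip: FeatureMap) -> FeatureMap:
        if low.stage_scale != 2 * skip.stage_scale:
            raise ShapeError(
                f"fusion expects low at twice the skip scale, got "
                f"{low.stage_scale} vs {skip.stage_scale}"
            )
        up = self.up(low.values)
        if up.shape[1:] != tuple(skip.spatial_shape):
            raise ShapeError(
                f"upsampled shape {up.shape[1:]} does not match skip "
                f"{tuple(skip.spatial_shape)}"
            )
        cat = ad.concat([up, skip.values], axis=0)
        scale = skip.stage_scale
        h = ad.gelu(self._norm(self.conv1(cat), self.norm1, scale))
        h = self._norm(self.conv2(h), self.norm2, scale)
        return FeatureMap(ad.gelu(self.shortcut(cat) + h), scale)


class SegmentationHead(Module):
    """1x1x1 convolution + per-voxel softmax over classes."""

    def __init__(self, in_channels: int, n_classes: int, rng, dtype=np.float32):
        self.n_classes = n_classes
        self.conv = Conv3d(in_channels, n_classes, 1, rng, dtype=dtype)

    def forward(self, fm: FeatureMap) -> Tensor:
        if fm.stage_scale != 1:
            raise ContractError(
                f"segmentation head requires original-scale features, "
                f"got stage_scale={fm.stage_scale}"
            )
        logits = self.conv(fm.values)  # (n_classes, H, W, D)
        c = self.n_classes
        h, w, d = logits.shape[1:]
        flat = logits.reshape(c, h * w * d).transpose(1, 0)
        probs = ad.softmax(flat, axis=-1)
        return probs.transpose(1, 0).reshape(c, h, w, d)


class Decoder(Module):
    """Walk the pyramid 16 -> 8 -> 4 -> 2 -> 1 with fusion + DW-Conv refinement."""

    def __init__(self, stage_widths: tuple[int, ...], cfg: DecoderConfig,
                 rng=None, dtype=np.float32):
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(0)
        w1, w2, w3, w4 = stage_widths

        def make_block(c):
            if cfg.block_type == "dwconv":
                return DWConvBlock(c, rng, cfg.dw_kernel_length, dtype=dtype)
            return PlainResidualBlock(c, rng, dtype=dtype)

        self.fuse8 = UpsampleFuse(w4, w3, rng, dtype=dtype)
        self.block8 = make_block(w3)
        self.fuse4 = UpsampleFuse(w3, w2, rng, dtype=dtype)
        self.block4 = make_block(w2)
        self.fuse2 = UpsampleFuse(w2, w1, rng, dtype=dtype)
        self.block2 = make_block(w1)
        self.up_final = ConvTranspose3d(w1, cfg.head_width, rng, stride=2, dtype=dtype)
        self.block1 = make_block(cfg.head_width)
        self.head = SegmentationHead(cfg.head_width, cfg.n_classes, rng, dtype=dtype)

    def forward(self, pyramid: list[FeatureMap]) -> Tensor:
        if len(pyramid) != 4:
            raise ValidationError(f"expected a 4-level pyramid, got {len(pyramid)} levels")
        scales = [fm.stage_scale for fm in pyramid]
        if scales != [2, 4, 8, 16]:
            raise ValidationError(f"pyramid scales must be [2,4,8,16], got {scales}")
        s2, s4, s8, s16 = pyramid
        x = self.block8(self.fuse8(s16, s8))
        x = self.block4(self.fuse4(x, s4))
        x = self.block2(self.fuse2(x, s2))
        x = FeatureMap(self.up_final(x.values), 1)
        x = self.block1(x)
        return self.head(x)
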