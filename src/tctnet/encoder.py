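"""Hybrid Transformer-CNN encoder.

The encoder follows the four-stage hierarchical design of modern vision
backbones. A Stem block (7x7x7 convolution, stride 2, padding 3, layer norm,
GELU) halves the input resolution and injects local inductive bias, which is
what allows the design to drop positional encoding entirely. Stride-2
convolutional patch embeddings sit between stages, so the four stage outputs
live at 1/2, 1/4, 1/8 and 1/16 of the input resolution.

Each stage stacks Convolution Transformer (CT) blocks: a pre-norm vanilla
transformer block whose queries are the tokens themselves and whose keys and
values come from a *convolutional projection* — the token sequence is
reshaped back to a 3D grid, passed through a depth-wise convolution of
stride k (the per-stage reduction rate), and flattened again, shrinking the
key/value sequence by k^3. With reduction rates (8, 4, 2, 1) against stage
scales (2, 4, 8, 16), keys and values have the same spatial size at every
stage (1/16 of the input per axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import EncoderConfig
from .errors import ShapeError, ValidationError
from .nn import Conv3d, LayerNorm, Linear, Module

__all__ = [
    "FeatureMap",
    "TokenSequence",
    "AttentionConfig",
    "StemBlock",
    "ConvPatchEmbed",
    "ConvProjection",
    "MultiHeadAttention",
    "CTBlock",
    "Encoder",
    "map_to_tokens",
    "tokens_to_map",
]


@dataclass
class FeatureMap:
    """A channels x H x W x D feature grid at a known downsampling factor."""

    values: Tensor
    stage_scale: int = 1

    def __post_init__(self):
        if not isinstance(self.values, Tensor):
            self.values = Tensor(np.asarray(self.values))
        if self.values.ndim != 4:
            raise ShapeError(f"FeatureMap expects C x H x W x D, got {self.values.shape}")
        if self.stage_scale not in (1, 2, 4, 8, 16):
            raise ValidationError(f"stage_scale must be in {{1,2,4,8,16}}, got {self.stage_scale}")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]


@dataclass
class TokenSequence:
    """An L x C token array remembering the 3D grid it was flattened from."""

    values: Tensor
    spatial_shape: tuple[int, int, int]

    def __post_init__(self):
        if not isinstance(self.values, Tensor):
            self.values = Tensor(np.asarray(self.values))
        h, w, d = self.spatial_shape
        if self.values.ndim != 2 or self.values.shape[0] != h * w * d:
            raise ShapeError(
                f"TokenSequence length {self.values.shape} inconsistent with "
                f"spatial shape {self.spatial_shape}"
            )

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def channels(self) -> int:
        return self.values.shape[1]


@dataclass
class AttentionConfig:
    """Multi-head attention geometry for one stage."""

    heads: int
    reduction: int
    channels: int

    def __post_init__(self):
        if self.channels % self.heads:
            raise ValidationError(
                f"channels {self.channels} not divisible by heads {self.heads}"
            )

    @property
    def head_dim(self) -> int:
        return self.channels // self.heads


def map_to_tokens(fm: FeatureMap) -> TokenSequence:
    c = fm.channels
    h, w, d = fm.spatial_shape
    vals = fm.values.transpose(1, 2, 3, 0).reshape(h * w * d, c)
    return TokenSequence(vals, (h, w, d))


def tokens_to_map(seq: TokenSequence, stage_scale: int) -> FeatureMap:
    h, w, d = seq.spatial_shape
    vals = seq.values.reshape(h, w, d, seq.channels).transpose(3, 0, 1, 2)
    return FeatureMap(vals, stage_scale)


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.isfinite(arr).all():
        raise ValidationError(f"{what} contains non-finite values")


def _check_even(shape, what: str) -> None:
    for axis, s in enumerate(shape):
        if s < 2 or s % 2:
            raise ShapeError(
                f"{what}: spatial axis {axis} has size {s}; stride-2 downsampling "
                f"requires even sizes >= 2"
            )


class StemBlock(Module):
    """7x7x7 stride-2 convolution + channel layer norm + GELU."""

    def __init__(self, in_channels: int, stem_width: int, rng, dtype=np.float32):
        self.conv = Conv3d(in_channels, stem_width, 7, rng, stride=2, padding=3, dtype=dtype)
        self.norm = LayerNorm(stem_width, dtype=dtype)

    def forward(self, patch: Tensor | np.ndarray) -> FeatureMap:
        x = patch if isinstance(patch, Tensor) else Tensor(np.asarray(patch))
        if x.ndim != 4:
            raise ShapeError(f"stem expects C x H x W x D input, got {x.shape}")
        _check_finite(x.data, "stem input")
        _check_even(x.shape[1:], "stem")
        fm = FeatureMap(self.conv(x), stage_scale=2)
        seq = map_to_tokens(fm)
        seq = TokenSequence(ad.gelu(self.norm(seq.values)), seq.spatial_shape)
        return tokens_to_map(seq, 2)


class ConvPatchEmbed(Module):
    """Non-overlapping 2x2x2 stride-2 convolution + layer norm; halves resolution."""

    def __init__(self, in_channels: int, out_width: int, rng, dtype=np.float32):
        self.conv = Conv3d(in_channels, out_width, 2, rng, stride=2, dtype=dtype)
        self.norm = LayerNorm(out_width, dtype=dtype)

    def forward(self, fm: FeatureMap) -> FeatureMap:
        _check_even(fm.spatial_shape, "patch embedding")
        out = FeatureMap(self.conv(fm.values), stage_scale=fm.stage_scale * 2)
        seq = map_to_tokens(out)
        seq = TokenSequence(self.norm(seq.values), seq.spatial_shape)
        return tokens_to_map(seq, out.stage_scale)


class ConvProjection(Module):
    """Produce Q, K, V for attention via convolutional projection.

    Queries keep the full token sequence. Keys and values are obtained by
    Flatten(DWConv3D(Reshape3D(x))) with a depth-wise convolution of kernel
    and stride k, shrinking their length by k^3; K and V use two separate
    depth-wise convolutions. All three then pass through learned pointwise
    projections before head splitting.
    """

    def __init__(self, channels: int, reduction: int, rng, dtype=np.float32):
        self.reduction = int(reduction)
        self.dw_k = Conv3d(channels, channels, self.reduction, rng,
                           stride=self.reduction, groups=channels, dtype=dtype)
        self.dw_v = Conv3d(channels, channels, self.reduction, rng,
                           stride=self.reduction, groups=channels, dtype=dtype)
        self.proj_q = Linear(channels, channels, rng, dtype=dtype)
        self.proj_k = Linear(channels, channels, rng, dtype=dtype)
        self.proj_v = Linear(channels, channels, rng, dtype=dtype)

    def reduce(self, seq: TokenSequence, which: str) -> TokenSequence:
        """Depth-wise reduction only (no pointwise projection) — used in tests."""
        k = self.reduction
        h, w, d = seq.spatial_shape
        for axis, s in zip("HWD", (h, w, d)):
            if s % k:
                raise ShapeError(
                    f"reduction rate k={k} does not divide spatial axis {axis}={s}"
                )
        grid = tokens_to_map(seq, 1).values
        conv = self.dw_k if which == "k" else self.dw_v
        red = FeatureMap(conv(grid), 1)
        return map_to_tokens(red)

    def forward(self, seq: TokenSequence) -> tuple[TokenSequence, TokenSequence, TokenSequence]:
        q = TokenSequence(self.proj_q(seq.values), seq.spatial_shape)
        k_red = self.reduce(seq, "k")
        v_red = self.reduce(seq, "v")
        k = TokenSequence(self.proj_k(k_red.values), k_red.spatial_shape)
        v = TokenSequence(self.proj_v(v_red.values), v_red.spatial_shape)
        return q, k, v


class MultiHeadAttention(Module):
    """Scaled dot-product attention over pre-projected Q, K, V token sequences."""

    def __init__(self, channels: int, heads: int, rng, dtype=np.float32):
        self.heads = int(heads)
        self.channels = int(channels)
        self.merge = Linear(channels, channels, rng, dtype=dtype)

    def forward(self, q: TokenSequence, k: TokenSequence, v: TokenSequence) -> TokenSequence:
        if q.channels != k.channels or q.channels != v.channels:
            raise ShapeError(
                f"Q/K/V channel mismatch: {q.channels}, {k.channels}, {v.channels}"
            )
        n = self.heads
        c = q.channels
        d = c // n
        lq, lk = q.length, k.length

        def split(seq: TokenSequence, ln: int) -> Tensor:
            return seq.values.reshape(ln, n, d).transpose(1, 0, 2)  # (n, L, d)

        qh, kh, vh = split(q, lq), split(k, lk), split(v, lk)
        logits = ad.matmul(qh, kh.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))
        attn = ad.softmax(logits, axis=-1)
        out = ad.matmul(attn, vh)                         # (n, Lq, d)
        merged = out.transpose(1, 0, 2).reshape(lq, c)    # concat heads
        return TokenSequence(self.merge(merged), q.spatial_shape)

    def attention_weights(self, q: TokenSequence, k: TokenSequence) -> np.ndarray:
        """Softmax attention matrix (heads x Lq x Lk), for inspection/tests."""
        n, d = self.heads, q.channels // self.heads
        qh = q.values.data.reshape(q.length, n, d).transpose(1, 0, 2)
        kh = k.values.data.reshape(k.length, n, d).transpose(1, 0, 2)
        logits = qh @ kh.transpose(0, 2, 1) / np.sqrt(d)
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)


class MLP(Module):
    def __init__(self, channels: int, mlp_ratio: float, rng, dtype=np.float32):
        hidden = int(round(channels * mlp_ratio))
        self.fc1 = Linear(channels, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


class CTBlock(Module):
    """Convolution Transformer block: pre-norm MHSA (conv projection) + MLP.

    No positional encoding anywhere; with k=1 the block is permutation-
    equivariant over token order.
    """

    def __init__(self, channels: int, heads: int, reduction: int, mlp_ratio: float,
                 rng, dtype=np.float32):
        self.att = AttentionConfig(heads=heads, reduction=reduction, channels=channels)
        self.norm1 = LayerNorm(channels, dtype=dtype)
        self.proj = ConvProjection(channels, reduction, rng, dtype=dtype)
        self.mhsa = MultiHeadAttention(channels, heads, rng, dtype=dtype)
        self.norm2 = LayerNorm(channels, dtype=dtype)
        self.mlp = MLP(channels, mlp_ratio, rng, dtype=dtype)

    def forward(self, seq: TokenSequence) -> TokenSequence:
        normed = TokenSequence(self.norm1(seq.values), seq.spatial_shape)
        q, k, v = self.proj(normed)
        x = seq.values + self.mhsa(q, k, v).values
        x = x + self.mlp(self.norm2(x))
        return TokenSequence(x, seq.spatial_shape)


class Encoder(Module):
    """Stem + four stages of CT blocks, returning the 4-level feature pyramid."""

    def __init__(self, in_channels: int, cfg: EncoderConfig, rng=None, dtype=np.float32):
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.stem = StemBlock(in_channels, cfg.stem_width, rng, dtype=dtype)
        self.embeds: list[Module] = []
        self.stages: list[list[CTBlock]] = []
        prev = cfg.stem_width
        for i in range(4):
            width = cfg.stage_widths[i]
            if i == 0 and prev != width:
                # stem feeds stage 1 directly; align widths with a pointwise embed
                self.embeds.append(Conv3d(prev, width, 1, rng, dtype=dtype))
            elif i == 0:
                self.embeds.append(None)
            else:
                self.embeds.append(ConvPatchEmbed(prev, width, rng, dtype=dtype))
            self.stages.append([
                CTBlock(width, cfg.stage_heads[i], cfg.stage_reductions[i],
                        cfg.mlp_ratio, rng, dtype=dtype)
                for _ in range(cfg.stage_depths[i])
            ])
            prev = width

    def named_parameters(self, prefix: str = ""):
        yield from self.stem.named_parameters(f"{prefix}stem.")
        for i, emb in enumerate(self.embeds):
            if emb is not None:
                yield from emb.named_parameters(f"{prefix}embeds.{i}.")
        for i, blocks in enumerate(self.stages):
            for j, blk in enumerate(blocks):
                yield from blk.named_parameters(f"{prefix}stages.{i}.{j}.")

    def forward(self, patch: Tensor | np.ndarray) -> list[FeatureMap]:
        x = patch if isinstance(patch, Tensor) else Tensor(np.asarray(patch))
        for axis, s in enumerate(x.shape[1:]):
            if s % 16:
                raise ShapeError(
                    f"encoder input spatial axis {axis} has size {s}; "
                    f"the 4-stage ladder requires divisibility by 16"
                )
        fm = self.stem(x)
        pyramid: list[FeatureMap] = []
        for i in range(4):
            emb = self.embeds[i]
            if emb is not None:
                fm = emb(fm) if isinstance(emb, ConvPatchEmbed) else FeatureMap(
                    emb(fm.values), fm.stage_scale
                )
            seq = map_to_tokens(fm)
            for blk in self.stages[i]:
                seq = blk(seq)
            fm = tokens_to_map(seq, fm.stage_scale)
            pyramid.append(fm)
        return pyramid
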