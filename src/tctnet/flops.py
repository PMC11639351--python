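"""Analytic forward-pass flop accounting.

Convention: one multiply-add = 2 flops; convolution and matrix-multiply
terms only (layer norms, activations, softmax and bias additions are
ignored, the dominant-term convention of common profilers). Because the
convention itself is a choice, the report also carries the multiply-add
total (``total_gmacs``), which is exactly half.

The counter walks the configuration analytically — no arrays are allocated
— and is cross-checked in the test suite against an instrumented forward
pass (:class:`tctnet.autodiff.FlopMeter`) that counts the same primitive
classes from actual runtime shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ModelConfig
from .errors import ValidationError

__all__ = ["FlopReport", "count_flops", "conv_flops", "attention_flops"]


@dataclass
class FlopReport:
    entries: list[tuple[str, int]] = field(default_factory=list)
    convention: str = "one multiply-add = 2 flops; conv and matmul terms only"

    def add(self, name: str, flops: int) -> None:
        if flops < 0:
            raise ValidationError(f"negative flop count for {name}")
        self.entries.append((name, int(flops)))

    @property
    def total_flops(self) -> int:
        return sum(f for _, f in self.entries)

    @property
    def total_gflops(self) -> float:
        return self.total_flops / 1e9

    @property
    def total_gmacs(self) -> float:
        return self.total_flops / 2e9

    def as_dict(self) -> dict:
        return {
            "convention": self.convention,
            "total_gflops": self.total_gflops,
            "total_gmacs": self.total_gmacs,
            "per_layer": {name: f for name, f in self.entries},
        }

    def table(self) -> str:
        width = max(len(n) for n, _ in self.entries) if self.entries else 10
        lines = [f"{'layer':<{width}}  GFlops"]
        for name, f in self.entries:
            lines.append(f"{name:<{width}}  {f / 1e9:10.3f}")
        lines.append(f"{'TOTAL':<{width}}  {self.total_gflops:10.3f}")
        lines.append(f"{'(GMacs)':<{width}}  {self.total_gmacs:10.3f}")
        return "\n".join(lines)


def conv_flops(cin: int, cout: int, kernel_voxels: int, out_voxels: int,
               groups: int = 1) -> int:
    """2 * Cin/G * Cout * prod(kernel) * prod(out spatial)."""
    return 2 * (cin // groups) * cout * kernel_voxels * out_voxels


def attention_flops(lq: int, lkv: int, channels: int) -> int:
    """QK^T plus AV, summed over heads: 2 * (2 * Lq * Lkv * C)."""
    return 2 * 2 * lq * lkv * channels


def count_flops(cfg: ModelConfig, input_shape: tuple[int, ...] = (4, 128, 128, 128)
                ) -> FlopReport:
    """Analytic flop count for one forward pass on `input_shape` input."""
    c1, h, w, d = input_shape
    if c1 != cfg.in_channels:
        raise ValidationError(
            f"input has {c1} channels but the model expects {cfg.in_channels}"
        )
    for s in (h, w, d):
        if s % 16:
            raise ValidationError(f"spatial size {s} not divisible by 16")
    enc = cfg.encoder
    rep = FlopReport()

    def vox(scale: int) -> int:
        return (h // scale) * (w // scale) * (d // scale)

    # -- encoder -----------------------------------------------------------
    rep.add("stem.conv7x7x7", conv_flops(c1, enc.stem_width, 343, vox(2)))
    prev = enc.stem_width
    for i in range(4):
        scale = 2 ** (i + 1)
        width = enc.stage_widths[i]
        name = f"enc.stage{i + 1}"
        if i == 0:
            if prev != width:
                rep.add(f"{name}.align1x1x1", conv_flops(prev, width, 1, vox(2)))
        else:
            rep.add(f"{name}.embed2x2x2", conv_flops(prev, width, 8, vox(scale)))
        lq = vox(scale)
        k = enc.stage_reductions[i]
        lkv = vox(scale * k)
        for b in range(enc.stage_depths[i]):
            blk = f"{name}.block{b + 1}"
            # two separate depth-wise reductions for K and V (kernel k, stride k)
            rep.add(f"{blk}.dwconv_kv", 2 * conv_flops(width, width, k ** 3, lkv,
                                                       groups=width))
            rep.add(f"{blk}.proj_q", conv_flops(width, width, 1, lq))
            rep.add(f"{blk}.proj_kv", 2 * conv_flops(width, width, 1, lkv))
            rep.add(f"{blk}.attention", attention_flops(lq, lkv, width))
            rep.add(f"{blk}.merge", conv_flops(width, width, 1, lq))
            hidden = int(round(width * enc.mlp_ratio))
            rep.add(f"{blk}.mlp", conv_flops(width, hidden, 1, lq)
                    + conv_flops(hidden, width, 1, lq))
        prev = width

    # -- decoder -----------------------------------------------------------
    w1, w2, w3, w4 = enc.stage_widths
    dec = cfg.decoder
    a = dec.dw_kernel_length

    def fuse(name: str, cin: int, cout: int, out_scale: int) -> None:
        v = vox(out_scale)
        rep.add(f"{name}.upsample", conv_flops(cin, cout, 8, vox(out_scale * 2)))
        rep.add(f"{name}.conv1", conv_flops(2 * cout, cout, 27, v))
        rep.add(f"{name}.conv2", conv_flops(cout, cout, 27, v))
        rep.add(f"{name}.shortcut", conv_flops(2 * cout, cout, 1, v))

    def block(name: str, c: int, scale: int) -> None:
        v = vox(scale)
        if dec.block_type == "dwconv":
            rep.add(f"{name}.directional", 6 * 3 * conv_flops(c, c, a, v, groups=c))
            rep.add(f"{name}.project", conv_flops(6 * c, c, 1, v))
        else:
            rep.add(f"{name}.conv1", conv_flops(c, c, 27, v))
            rep.add(f"{name}.conv2", conv_flops(c, c, 27, v))

    fuse("dec.fuse8", w4, w3, 8)
    block("dec.block8", w3, 8)
    fuse("dec.fuse4", w3, w2, 4)
    block("dec.block4", w2, 4)
    fuse("dec.fuse2", w2, w1, 2)
    block("dec.block2", w1, 2)
    rep.add("dec.up_final", conv_flops(w1, dec.head_width, 8, vox(2)))
    block("dec.block1", dec.head_width, 1)
    rep.add("dec.head1x1x1", conv_flops(dec.head_width, cfg.n_classes, 1, vox(1)))
    return rep
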