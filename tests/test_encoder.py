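"""Encoder: stem, patch embedding, convolutional projection, attention, CT blocks."""

import numpy as np
import pytest

from tctnet.autodiff import Tensor
from tctnet.config import EncoderConfig
from tctnet.encoder import (AttentionConfig, ConvPatchEmbed, ConvProjection,
                            CTBlock, Encoder, FeatureMap, MultiHeadAttention,
                            StemBlock, TokenSequence, map_to_tokens,
                            tokens_to_map)
from tctnet.errors import ShapeError, ValidationError

RNG = np.random.default_rng(0)


def naive_attention(q, k, v, heads):
    """Three-loop dense attention oracle, independent of the vectorised path."""
    lq, c = q.shape
    lk = k.shape[0]
    d = c // heads
    out = np.zeros((lq, c))
    for h in range(heads):
        qs, ks, vs = (m[:, h * d:(h + 1) * d] for m in (q, k, v))
        for i in range(lq):
            logits = np.array([qs[i] @ ks[j] / np.sqrt(d) for j in range(lk)])
            weights = np.exp(logits - logits.max())
            weights /= weights.sum()
            for j in range(lk):
                out[i, h * d:(h + 1) * d] += weights[j] * vs[j]
    return out


# ---------------------------------------------------------------------------
# stem


def test_stem_halves_resolution_and_sets_width(rng):
    stem = StemBlock(4, 8, rng)
    out = stem(rng.random((4, 32, 32, 32), dtype=np.float32))
    assert out.values.shape == (8, 16, 16, 16)
    assert out.stage_scale == 2


def test_stem_errors_name_the_failing_axis(rng):
    stem = StemBlock(1, 4, rng)
    with pytest.raises(ShapeError, match="axis 1"):
        stem(np.zeros((1, 8, 7, 8), dtype=np.float32))
    bad = np.zeros((1, 8, 8, 8), dtype=np.float32)
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValidationError, match="non-finite"):
        stem(bad)


def test_stem_zero_input_is_spatially_constant(rng):
    """Zero input with zero bias -> GELU(LayerNorm(0)) per channel, constant."""
    stem = StemBlock(2, 4, rng)
    stem.conv.bias.data[:] = 0.0
    out = stem(np.zeros((2, 16, 16, 16), dtype=np.float32)).values.data
    for c in range(4):
        assert np.ptp(out[c]) == 0.0


# ---------------------------------------------------------------------------
# patch embedding


def test_patch_embed_halves_and_doubles_scale(rng):
    embed = ConvPatchEmbed(3, 6, rng)
    fm = FeatureMap(Tensor(rng.random((3, 8, 8, 8), dtype=np.float32)), stage_scale=2)
    out = embed(fm)
    assert out.values.shape == (6, 4, 4, 4)
    assert out.stage_scale == 4
    with pytest.raises(ShapeError):
        embed(FeatureMap(Tensor(np.zeros((3, 7, 8, 8), dtype=np.float32)), 2))


def test_embedding_ladder_reaches_all_four_scales(rng):
    """Stem then three embeds on a 64^3 input walk scales 2, 4, 8, 16."""
    stem = StemBlock(1, 4, rng)
    fm = stem(rng.random((1, 64, 64, 64), dtype=np.float32))
    scales = [fm.stage_scale]
    widths = (8, 16, 32)
    for w in widths:
        fm = ConvPatchEmbed(fm.channels, w, rng)(fm)
        scales.append(fm.stage_scale)
    assert scales == [2, 4, 8, 16]
    assert fm.values.shape == (32, 4, 4, 4)


# ---------------------------------------------------------------------------
# convolutional projection


def test_conv_projection_kv_lengths_shrink_by_k_cubed(rng):
    proj = ConvProjection(4, 2, rng)
    seq = TokenSequence(Tensor(rng.random((8 * 8 * 8, 4), dtype=np.float32)), (8, 8, 8))
    q, k, v = proj(seq)
    assert q.length == 512
    assert k.length == v.length == 512 // 8
    proj1 = ConvProjection(4, 1, rng)
    q, k, v = proj1(seq)
    assert k.length == q.length == v.length == 512


def test_conv_projection_stage1_published_lengths(rng):
    """Stage 1 of a 128^3 crop: H=W=D=64, k=8 -> K/V length 512, Q 262144."""
    att = AttentionConfig(heads=2, reduction=8, channels=2)
    proj = ConvProjection(att.channels, att.reduction, rng)
    seq = TokenSequence(
        Tensor(np.zeros((64 ** 3, 2), dtype=np.float32)), (64, 64, 64)
    )
    q, k, v = proj(seq)
    assert q.length == 262144 and k.length == 512 and v.length == 512


def test_conv_projection_rejects_non_dividing_k(rng):
    proj = ConvProjection(2, 4, rng)
    seq = TokenSequence(Tensor(np.zeros((6 * 6 * 6, 2), dtype=np.float32)), (6, 6, 6))
    with pytest.raises(ShapeError, match="k=4"):
        proj(seq)


def test_delta_kernel_reduction_is_identity(rng):
    """k=1 depth-wise weights set to a delta -> reduction leaves tokens unchanged."""
    proj = ConvProjection(3, 1, rng)
    proj.dw_k.weight.data[:] = 1.0  # kernel is 1x1x1 per channel
    proj.dw_k.bias.data[:] = 0.0
    seq = TokenSequence(Tensor(rng.random((4 * 4 * 4, 3), dtype=np.float32)), (4, 4, 4))
    red = proj.reduce(seq, "k")
    np.testing.assert_allclose(red.values.data, seq.values.data, rtol=1e-6)


# ---------------------------------------------------------------------------
# attention


@pytest.mark.parametrize("heads,reduction", [(2, 8), (4, 4), (8, 2), (16, 1)],
                         ids=["stage1", "stage2", "stage3", "stage4"])
def test_attention_matches_naive_oracle(heads, reduction, rng):
    """Vectorised attention equals a three-loop oracle on small token sets."""
    c = 16 * heads // 8 if heads >= 8 else 16
    c = max(c, heads)
    mha = MultiHeadAttention(c, heads, rng, dtype=np.float64)
    q = rng.standard_normal((6, c))
    k = rng.standard_normal((3, c))
    v = rng.standard_normal((3, c))
    mk = lambda a, s: TokenSequence(Tensor(a), s)
    out = mha(mk(q, (1, 2, 3)), mk(k, (1, 1, 3)), mk(v, (1, 1, 3))).values.data
    # undo the output merge to compare the raw attention result
    raw = (out - mha.merge.bias.data) @ np.linalg.inv(mha.merge.weight.data)
    np.testing.assert_allclose(raw, naive_attention(q, k, v, heads), atol=1e-5)


def test_single_key_attention_broadcasts_value(rng):
    mha = MultiHeadAttention(4, 2, rng, dtype=np.float64)
    mha.merge.weight.data = np.eye(4)
    mha.merge.bias.data[:] = 0.0
    q = rng.standard_normal((5, 4))
    k = rng.standard_normal((1, 4))
    v = rng.standard_normal((1, 4))
    mk = lambda a, s: TokenSequence(Tensor(a), s)
    out = mha(mk(q, (5, 1, 1)), mk(k, (1, 1, 1)), mk(v, (1, 1, 1))).values.data
    np.testing.assert_allclose(out, np.broadcast_to(v, (5, 4)), atol=1e-12)


def test_attention_rows_sum_to_one_and_small_scale_limit(rng):
    mha = MultiHeadAttention(4, 2, rng, dtype=np.float64)
    q = rng.standard_normal((6, 4))
    k = rng.standard_normal((4, 4))
    mk = lambda a, s: TokenSequence(Tensor(a), s)
    w = mha.attention_weights(mk(q, (1, 2, 3)), mk(k, (1, 2, 2)))
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
    # scaling Q and K by c -> logits scale by c^2; c -> 0 gives the uniform average
    w0 = mha.attention_weights(mk(q * 1e-8, (1, 2, 3)), mk(k * 1e-8, (1, 2, 2)))
    np.testing.assert_allclose(w0, 1.0 / 4, atol=1e-16)


# ---------------------------------------------------------------------------
# CT block


def test_ct_block_preserves_shape(rng):
    blk = CTBlock(8, 2, 2, 4.0, rng)
    seq = TokenSequence(Tensor(rng.random((4 * 4 * 4, 8), dtype=np.float32)), (4, 4, 4))
    out = blk(seq)
    assert out.values.shape == seq.values.shape
    assert out.spatial_shape == seq.spatial_shape


def test_ct_block_with_zero_output_projections_is_identity(rng):
    blk = CTBlock(8, 2, 1, 4.0, rng)
    blk.mhsa.merge.weight.data[:] = 0.0
    blk.mhsa.merge.bias.data[:] = 0.0
    blk.mlp.fc2.weight.data[:] = 0.0
    blk.mlp.fc2.bias.data[:] = 0.0
    seq = TokenSequence(Tensor(rng.random((27, 8), dtype=np.float32)), (3, 3, 3))
    np.testing.assert_allclose(blk(seq).values.data, seq.values.data, atol=1e-7)


def test_ct_block_is_permutation_equivariant_without_positional_encoding(rng):
    """With k=1 a spatial permutation of tokens permutes the output identically."""
    blk = CTBlock(6, 2, 1, 2.0, rng, dtype=np.float64)
    tokens = rng.standard_normal((8, 6))
    perm = rng.permutation(8)
    out = blk(TokenSequence(Tensor(tokens), (2, 2, 2))).values.data
    out_perm = blk(TokenSequence(Tensor(tokens[perm]), (2, 2, 2))).values.data
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)


# ---------------------------------------------------------------------------
# full encoder


def test_encoder_pyramid_shapes_and_scales(rng):
    cfg = EncoderConfig(stage_widths=(8, 16, 32, 64), stem_width=8)
    enc = Encoder(4, cfg, rng)
    pyramid = enc(rng.random((4, 32, 32, 32), dtype=np.float32))
    assert [fm.stage_scale for fm in pyramid] == [2, 4, 8, 16]
    assert [fm.values.shape for fm in pyramid] == [
        (8, 16, 16, 16), (16, 8, 8, 8), (32, 4, 4, 4), (64, 2, 2, 2)
    ]


def test_encoder_kv_resolution_uniform_across_stages():
    """scale x reduction = 16 at every stage, so K/V share one spatial size."""
    cfg = EncoderConfig()
    for i, k in enumerate(cfg.stage_reductions):
        assert 2 ** (i + 1) * k == 16


def test_encoder_rejects_indivisible_input(rng):
    enc = Encoder(1, EncoderConfig(stage_widths=(8, 16, 32, 64), stem_width=8), rng)
    with pytest.raises(ShapeError, match="divisib"):
        enc(np.zeros((1, 24, 32, 32), dtype=np.float32))


def test_encoder_forward_is_deterministic():
    cfg = EncoderConfig(stage_widths=(8, 16, 32, 64), stem_width=8, seed=5)
    x = np.random.default_rng(2).random((2, 32, 32, 32)).astype(np.float64)
    out1 = Encoder(2, cfg, dtype=np.float64)(x)[-1].values.data
    out2 = Encoder(2, cfg, dtype=np.float64)(x)[-1].values.data
    assert np.array_equal(out1, out2)


def test_token_map_round_trip(rng):
    fm = FeatureMap(Tensor(rng.random((3, 2, 4, 5), dtype=np.float32)), 2)
    back = tokens_to_map(map_to_tokens(fm), 2)
    np.testing.assert_array_equal(back.values.data, fm.values.data)
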