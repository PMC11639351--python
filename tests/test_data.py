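"""Intensity normalisation, cropping, augmentation, and NIfTI round trips."""

import numpy as np
import pytest
from scipy import stats

from tctnet.config import AugmentConfig
from tctnet.data import (LabelMap, PatchPair, Volume, augment,
                         label_guided_crop, load_labels, load_volume,
                         normalise_intensity, random_crop, save_prediction,
                         tumour_ratio)
from tctnet.errors import ShapeError, ValidationError
from tctnet.losses import regions_from_labels

# ---------------------------------------------------------------------------
# normalisation


def test_normalisation_percentile_mapping():
    """Foreground 0..100 uniform: p5=5, p95=95; 50 -> 0.5, 5 -> 0, 95 -> 1."""
    channel = np.zeros((11, 11, 1), dtype=np.float64)
    channel[:10, :10, 0] = np.arange(1, 101).reshape(10, 10)
    vol = Volume(channel[None])
    fg = channel[channel != 0]
    p5, p95 = np.percentile(fg, [5, 95])
    out = normalise_intensity(vol).intensities[0]
    expect = np.clip((channel - p5) / (p95 - p5), 0.0, 1.0)
    np.testing.assert_allclose(out, expect, atol=1e-6)
    # value 50 sits mid-range; extremes clip to the unit interval ends
    assert out[channel == 50.0][0] == pytest.approx((50 - p5) / (p95 - p5), abs=1e-6)
    assert out[channel == 100.0][0] == 1.0
    assert out[channel == 1.0][0] == 0.0


def test_normalisation_bounds_and_idempotence(rng):
    img = rng.random((2, 8, 8, 8)) * 1000
    out = normalise_intensity(Volume(img)).intensities
    assert out.min() >= 0.0 and out.max() <= 1.0
    # a channel whose foreground p5=0 and p95=1 maps through unchanged
    chan = np.zeros((101, 1, 1))
    chan[:100, 0, 0] = np.linspace(0.0, 1.0, 100)
    fg = chan[chan != 0]
    p5, p95 = np.percentile(fg, [5, 95])
    if abs(p5) < 1e-12 and abs(p95 - 1) < 1e-12:  # construction guard
        again = normalise_intensity(Volume(chan[None])).intensities
        np.testing.assert_allclose(again[0], chan, atol=1e-12)


def test_normalisation_errors():
    with pytest.raises(ValidationError, match="all zero"):
        normalise_intensity(Volume(np.zeros((1, 4, 4, 4))))
    flat = np.zeros((1, 4, 4, 4))
    flat[0, :2] = 7.0
    with pytest.raises(ValidationError, match="degenerate"):
        normalise_intensity(Volume(flat))


# ---------------------------------------------------------------------------
# cropping


def _toy_case(shape=(16, 16, 16), lesion=None):
    rng = np.random.default_rng(0)
    vol = Volume(rng.random((2,) + shape))
    labels = np.zeros(shape, dtype=np.int16)
    if lesion is not None:
        labels[lesion] = 2
    return vol, LabelMap(labels)


def test_full_volume_crop_is_the_identity(rng):
    vol, lab = _toy_case()
    pair = random_crop(vol, lab, (16, 16, 16), rng)
    assert pair.origin == (0, 0, 0)
    np.testing.assert_array_equal(pair.image, vol.intensities)


def test_crop_is_seed_deterministic():
    vol, lab = _toy_case()
    p1 = random_crop(vol, lab, (8, 8, 8), np.random.default_rng(5))
    p2 = random_crop(vol, lab, (8, 8, 8), np.random.default_rng(5))
    assert p1.origin == p2.origin


def test_crop_rejects_oversized_patch(rng):
    vol, lab = _toy_case()
    with pytest.raises(ShapeError, match="pad"):
        random_crop(vol, lab, (32, 16, 16), rng)


def test_random_crop_origin_is_uniform():
    """Chi-square on 10^4 origins over a 2x-oversized axis at alpha = 0.01."""
    vol, lab = _toy_case(shape=(16, 4, 4))
    rng = np.random.default_rng(99)
    n_positions = 16 - 8 + 1
    counts = np.zeros(n_positions)
    for _ in range(10_000):
        counts[random_crop(vol, lab, (8, 4, 4), rng).origin[0]] += 1
    assert stats.chisquare(counts).pvalue > 0.01


def test_label_guided_crop_centres_on_single_foreground_voxel(rng):
    vol, lab = _toy_case(lesion=(8, 8, 8))
    pair = label_guided_crop(vol, lab, (6, 6, 6), rng)
    assert pair.origin == (5, 5, 5)
    assert pair.labels[3, 3, 3] == 2


def test_label_guided_crop_always_contains_foreground(rng):
    vol, lab = _toy_case(lesion=(slice(0, 2), slice(14, 16), 3))
    for _ in range(20):
        pair = label_guided_crop(vol, lab, (4, 4, 4), rng)
        assert (pair.labels > 0).any()


def test_label_guided_crop_requires_foreground(rng):
    vol, lab = _toy_case()
    with pytest.raises(ValidationError, match="foreground"):
        label_guided_crop(vol, lab, (4, 4, 4), rng)


def test_guided_crops_enrich_tumour_over_random_crops():
    """Mean tumour ratio over 10 guided crops exceeds 10 random crops."""
    from tctnet.phantoms import PhantomSpec, generate_phantom

    vol, lab = generate_phantom(
        PhantomSpec(shape=(48, 48, 48), lesion_radius_range=(4.0, 5.0), seed=2)
    )
    rng = np.random.default_rng(0)
    guided = [label_guided_crop(vol, lab, (16, 16, 16), rng) for _ in range(10)]
    rand = [random_crop(vol, lab, (16, 16, 16), rng) for _ in range(10)]
    mean_ratio = lambda pairs: np.mean([tumour_ratio(p.labels, "WT") for p in pairs])
    assert mean_ratio(guided) > mean_ratio(rand)


# ---------------------------------------------------------------------------
# augmentation


def _pair(rng, shape=(8, 8, 8)):
    labels = (rng.random(shape) > 0.8).astype(np.int16) * 2
    return PatchPair(rng.random((2,) + shape).astype(np.float32), labels, (0, 0, 0))


def test_augment_with_zero_probabilities_is_identity(rng):
    pair = _pair(rng)
    out = augment(pair, rng, AugmentConfig.disabled())
    np.testing.assert_array_equal(out.image, pair.image)
    np.testing.assert_array_equal(out.labels, pair.labels)


def test_flip_is_an_involution(rng):
    pair = _pair(rng)
    cfg = AugmentConfig(prob_flip=1.0, prob_rot90=0, prob_scale=0,
                        prob_shift=0, prob_noise=0)
    once = augment(pair, np.random.default_rng(3), cfg)
    twice = augment(once, np.random.default_rng(3), cfg)
    np.testing.assert_array_equal(twice.image, pair.image)
    np.testing.assert_array_equal(twice.labels, pair.labels)


def test_spatial_augmentation_preserves_foreground_count(rng):
    pair = _pair(rng)
    cfg = AugmentConfig(prob_flip=0.5, prob_rot90=0.5, prob_scale=0,
                        prob_shift=0, prob_noise=0)
    for seed in range(5):
        out = augment(pair, np.random.default_rng(seed), cfg)
        assert (out.labels > 0).sum() == (pair.labels > 0).sum()


def test_spatial_augmentation_commutes_with_region_derivation(rng):
    labels = rng.choice([0, 1, 2, 4], size=(8, 8, 8)).astype(np.int16)
    pair = PatchPair(rng.random((1, 8, 8, 8)).astype(np.float32), labels, (0, 0, 0))
    cfg = AugmentConfig(prob_flip=1.0, prob_rot90=1.0, prob_scale=0,
                        prob_shift=0, prob_noise=0)
    out = augment(pair, np.random.default_rng(7), cfg)
    before = regions_from_labels(pair.labels)
    after = regions_from_labels(out.labels)
    # region masks of augmented labels == augmented region masks
    ref = augment(PatchPair(before.WT[None].astype(np.float32),
                            pair.labels, (0, 0, 0)),
                  np.random.default_rng(7), cfg)
    np.testing.assert_array_equal(after.WT, ref.image[0].astype(bool))


def test_intensity_ops_leave_labels_untouched(rng):
    pair = _pair(rng)
    cfg = AugmentConfig(prob_flip=0, prob_rot90=0, prob_scale=1.0,
                        prob_shift=1.0, prob_noise=1.0)
    out = augment(pair, rng, cfg)
    np.testing.assert_array_equal(out.labels, pair.labels)
    assert not np.array_equal(out.image, pair.image)


# ---------------------------------------------------------------------------
# tumour ratio


def test_tumour_ratio_counting():
    labels = np.zeros((2, 2, 2), dtype=np.int16)
    assert tumour_ratio(labels, "WT") == 0.0
    labels[:] = 4
    assert tumour_ratio(labels, "WT") == 1.0
    labels[:] = 0
    labels[0, 0, 0] = 2
    labels[0, 0, 1] = 2
    assert tumour_ratio(labels, "WT") == 0.25
    assert tumour_ratio(labels, "TC") == 0.0
    with pytest.raises(ValidationError):
        tumour_ratio(labels, "XX")


# ---------------------------------------------------------------------------
# NIfTI I/O


def test_nifti_round_trip(tmp_path, rng):
    img = rng.random((3, 6, 7, 8)).astype(np.float32)
    path = tmp_path / "case.nii.gz"
    save_prediction(path, img, spacing=(1.0, 1.0, 1.0))
    vol = load_volume(path)
    assert vol.intensities.shape == (3, 6, 7, 8)
    assert vol.spacing == (1.0, 1.0, 1.0)
    np.testing.assert_allclose(vol.intensities, img, atol=1e-7)


def test_nifti_label_round_trip_and_shape_check(tmp_path):
    labels = np.random.default_rng(0).choice([0, 1, 2, 4], size=(5, 5, 5))
    path = tmp_path / "label.nii.gz"
    save_prediction(path, labels.astype(np.int16))
    lab = load_labels(path, image_shape=(5, 5, 5))
    np.testing.assert_array_equal(lab.labels, labels)
    with pytest.raises(ShapeError, match="does not match"):
        load_labels(path, image_shape=(4, 5, 5))


def test_missing_file_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_volume(tmp_path / "absent.nii.gz")
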