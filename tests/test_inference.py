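"""Window planning, Gaussian importance weighting, sliding-window blending."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tctnet.data import Volume
from tctnet.errors import ContractError, ShapeError, ValidationError
from tctnet.inference import (gaussian_importance_map, plan_windows,
                              resize_twice_infer, sliding_window_infer)

# ---------------------------------------------------------------------------
# window planning


def test_single_window_when_roi_equals_volume():
    for overlap in (0.0, 0.25, 0.5):
        plan = plan_windows((128, 128, 128), (128, 128, 128), overlap)
        assert plan.origins == [(0, 0, 0)]


def test_two_windows_on_an_oversized_axis():
    """Volume (128,192,128), roi 128^3, overlap 0.5 -> origins {0, 64} on axis 1."""
    plan = plan_windows((128, 192, 128), (128, 128, 128), 0.5)
    assert plan.origins == [(0, 0, 0), (0, 64, 0)]


def test_plan_rejects_bad_inputs():
    with pytest.raises(ShapeError, match="pad"):
        plan_windows((64, 64, 64), (128, 64, 64), 0.5)
    with pytest.raises(ValidationError):
        plan_windows((64, 64, 64), (32, 32, 32), 1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    shape=st.tuples(*[st.integers(8, 40)] * 3),
    roi=st.tuples(*[st.integers(4, 8)] * 3),
    overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
)
def test_every_voxel_covered_by_at_least_one_window(shape, roi, overlap):
    plan = plan_windows(shape, roi, overlap)
    covered = np.zeros(shape, dtype=bool)
    for (x, y, z) in plan.origins:
        covered[x:x + roi[0], y:y + roi[1], z:z + roi[2]] = True
    assert covered.all()


# ---------------------------------------------------------------------------
# Gaussian importance map


@pytest.mark.parametrize("roi", [(8, 8, 8), (5, 7, 9), (16, 4, 12), (1, 3, 5)])
def test_gaussian_map_properties(roi):
    w = gaussian_importance_map(roi)
    assert w.shape == roi
    assert w.max() == 1.0
    centre = tuple((r - 1) // 2 for r in roi)
    assert w[centre] == pytest.approx(1.0, abs=1e-12) or max(
        w[centre], w[tuple(r // 2 for r in roi)]) == 1.0
    assert (w > 0).all()
    for axis in range(3):
        np.testing.assert_allclose(w, np.flip(w, axis=axis), atol=1e-12)


def test_gaussian_corner_below_centre():
    w = gaussian_importance_map((9, 9, 9))
    assert w[0, 0, 0] < w[4, 4, 4]


def test_gaussian_map_floor_prevents_zero_weights():
    w = gaussian_importance_map((64, 64, 64))
    assert w.min() >= 1e-3


def test_gaussian_map_validation():
    with pytest.raises(ValidationError):
        gaussian_importance_map((0, 4, 4))
    with pytest.raises(ValidationError):
        gaussian_importance_map((4, 4, 4), sigma_scale=0.0)


# ---------------------------------------------------------------------------
# sliding-window blending


def _softmaxify(rng, c, shape):
    logits = rng.random((c,) + shape)
    return (logits / logits.sum(axis=0)).astype(np.float32)


class EchoModel:
    """Deterministic stand-in model: probability = softmax of a fixed filter."""

    def __init__(self, c=3, seed=0):
        self.c = c
        self.rng = np.random.default_rng(seed)
        self.w = self.rng.standard_normal((c, 2))

    def __call__(self, window):
        feats = np.stack([window.mean(axis=0), window.std(axis=0)])
        logits = np.tensordot(self.w, feats, axes=([1], [0]))
        e = np.exp(logits - logits.max(axis=0, keepdims=True))
        return e / e.sum(axis=0, keepdims=True)


def test_single_window_equals_direct_forward(rng):
    model = EchoModel()
    image = rng.random((2, 16, 16, 16)).astype(np.float32)
    direct = model(image)
    for use_gaussian in (False, True):
        out = sliding_window_infer(image, model, (16, 16, 16), 0.5, use_gaussian)
        np.testing.assert_allclose(out, direct, atol=1e-6)


def test_constant_model_blends_to_the_constant(rng):
    const = np.array([0.1, 0.2, 0.7], dtype=np.float64)

    def model(window):
        return np.broadcast_to(const[:, None, None, None],
                               (3,) + window.shape[1:]).copy()

    image = rng.random((1, 20, 28, 20)).astype(np.float32)
    for overlap in (0.0, 0.5):
        for use_gaussian in (False, True):
            out = sliding_window_infer(image, model, (16, 16, 16),
                                       overlap, use_gaussian)
            np.testing.assert_allclose(
                out, np.broadcast_to(const[:, None, None, None], out.shape),
                atol=1e-6)


def naive_sliding_window(image, model, roi, overlap, use_gaussian):
    """Explicit-loop reference blender, independent of the library path."""
    from itertools import product

    shape = image.shape[1:]
    stride = [max(1, round(r * (1 - overlap))) for r in roi]
    axes_origins = []
    for s, r, st_ in zip(shape, roi, stride):
        origins = sorted(set(list(range(0, s - r + 1, st_)) + [s - r]))
        axes_origins.append(origins)
    if use_gaussian:
        w = np.ones(roi)
        for ax, r in enumerate(roi):
            centre = (r - 1) / 2
            sig = 0.125 * r
            line = np.exp(-0.5 * ((np.arange(r) - centre) / sig) ** 2)
            shape_ = [1, 1, 1]
            shape_[ax] = r
            w = w * line.reshape(shape_)
        w = np.maximum(w / w.max(), 1e-3)
    else:
        w = np.ones(roi)
    num = None
    den = np.zeros(shape)
    for ox, oy, oz in product(*axes_origins):
        win = image[:, ox:ox + roi[0], oy:oy + roi[1], oz:oz + roi[2]]
        p = model(win)
        if num is None:
            num = np.zeros((p.shape[0],) + shape)
        for c in range(p.shape[0]):
            for i in range(roi[0]):
                for j in range(roi[1]):
                    for k in range(roi[2]):
                        num[c, ox + i, oy + j, oz + k] += p[c, i, j, k] * w[i, j, k]
        den[ox:ox + roi[0], oy:oy + roi[1], oz:oz + roi[2]] += w
    return num / den


def test_agrees_with_naive_loop_oracle_on_two_window_volume(rng):
    model = EchoModel(seed=4)
    image = rng.random((2, 8, 12, 8)).astype(np.float64)
    for use_gaussian in (True, False):
        fast = sliding_window_infer(image, model, (8, 8, 8), 0.5, use_gaussian)
        slow = naive_sliding_window(image, model, (8, 8, 8), 0.5, use_gaussian)
        np.testing.assert_allclose(fast, slow, atol=1e-6)


def test_blended_probabilities_sum_to_one(rng):
    model = EchoModel(seed=1)
    image = rng.random((2, 20, 24, 28)).astype(np.float32)
    out = sliding_window_infer(image, model, (16, 16, 16), 0.5, True)
    np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-6)


def test_volume_smaller_than_roi_is_padded_and_cropped_back(rng):
    model = EchoModel(seed=2)
    image = rng.random((2, 10, 16, 12)).astype(np.float32)
    out = sliding_window_infer(image, model, (16, 16, 16), 0.5, True)
    assert out.shape == (3, 10, 16, 12)
    np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-5)


def test_model_contract_violation_is_reported(rng):
    def bad_model(window):
        return np.zeros((3, 2, 2, 2))

    with pytest.raises(ContractError, match="expected"):
        sliding_window_infer(rng.random((1, 8, 8, 8)).astype(np.float32),
                             bad_model, (8, 8, 8))


def test_resize_twice_baseline_returns_full_resolution_probabilities(rng):
    model = EchoModel(seed=3)
    vol = Volume(rng.random((2, 24, 24, 24)).astype(np.float32))
    out = resize_twice_infer(vol, model, (16, 16, 16))
    assert out.shape == (3, 24, 24, 24)
    np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-5)
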