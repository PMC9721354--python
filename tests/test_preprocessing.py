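"""Preprocessing: resampling, slice selection, normalization, crops, flips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cesynth.phantoms import Volume
from cesynth.preprocessing import (
    NormalizationSpec, SlicePair, apply_normalizer, augment_flip,
    crop_tumor_patch, crop_window, fit_normalizer, invert_normalizer,
    resample_isotropic, select_tumor_slices,
)


def _pair(h=16):
    rng = np.random.default_rng(0)
    mask = np.zeros((h, h), dtype=np.uint8)
    mask[4:7, 5:9] = 1
    return SlicePair(pre=rng.uniform(-1, 1, (h, h)).astype(np.float32),
                     ce=rng.uniform(-1, 1, (h, h)).astype(np.float32),
                     mask=mask)


# ------------------------------------------------------------- resampling
def test_resample_2mm_to_1mm_doubles_extent():
    v = Volume(np.random.default_rng(1).uniform(0, 1, (4, 6, 8)).astype(np.float32),
               spacing=(2.0, 2.0, 2.0))
    out = resample_isotropic(v, 1.0)
    assert out.spacing == (1.0, 1.0, 1.0)
    for o, i in zip(out.data.shape, v.data.shape):
        assert abs(o - 2 * i) <= 1


def test_resample_constant_volume_stays_constant():
    v = Volume(np.full((6, 10, 10), 2.5, dtype=np.float32), spacing=(2.0, 1.0, 1.0))
    out = resample_isotropic(v, 1.0)
    # interpolation preserves constants away from the zero-padded boundary
    assert np.allclose(out.data[2:-2, 2:-2, 2:-2], 2.5, atol=1e-4)


def test_resample_identity_spacing_keeps_array():
    data = np.random.default_rng(2).uniform(0, 1, (4, 8, 8)).astype(np.float32)
    out = resample_isotropic(Volume(data, spacing=(1.0, 1.0, 1.0)), 1.0)
    assert np.allclose(out.data, data, atol=1e-5)


def test_resample_mask_stays_binary():
    m = np.zeros((4, 8, 8), dtype=np.uint8)
    m[1:3, 2:5, 3:6] = 1
    out = resample_isotropic(Volume(m, spacing=(2.0, 2.0, 2.0), modality="mask"), 1.0)
    assert set(np.unique(out.data)) <= {0, 1}


def test_resample_rejects_bad_spacing():
    with pytest.raises(ValueError):
        resample_isotropic(Volume(np.zeros((2, 2, 2)), spacing=(0.0, 1.0, 1.0)), 1.0)


# ---------------------------------------------------------- slice selection
def test_select_tumor_slices_matches_scan():
    rng = np.random.default_rng(3)
    mask = (rng.uniform(size=(12, 8, 8)) > 0.93).astype(np.uint8)
    mask[5] = 0
    expected = [i for i in range(12) if mask[i].any()]
    assert select_tumor_slices(mask) == expected


def test_select_tumor_slices_span_and_empty():
    mask = np.zeros((20, 4, 4), dtype=np.uint8)
    mask[10:15, 1, 1] = 1
    assert select_tumor_slices(mask) == [10, 11, 12, 13, 14]
    assert select_tumor_slices(np.zeros((5, 4, 4), dtype=np.uint8)) == []


# ------------------------------------------------------------ normalization
def test_fit_normalizer_takes_global_max():
    a = np.full((4, 4), 3.0)
    b = np.full((4, 4), 7.5)
    assert fit_normalizer([a, b]).clip_max == 7.5
    assert fit_normalizer([np.full((2, 2), 4.0)]).clip_max == 4.0
    with pytest.raises(ValueError):
        fit_normalizer([])


def test_apply_normalizer_endpoints_and_clipping():
    spec = NormalizationSpec(clip_max=10.0)
    img = np.array([0.0, 5.0, 10.0, 20.0])
    out = apply_normalizer(img, spec)
    assert out.tolist() == [-1.0, 0.0, 1.0, 1.0]
    with pytest.raises(ValueError):
        apply_normalizer(np.array([-0.1]), spec)


def test_normalizer_roundtrip_below_clip():
    rng = np.random.default_rng(4)
    spec = NormalizationSpec(clip_max=6.0)
    img = rng.uniform(0, 6.0, (16, 16)).astype(np.float32)
    back = invert_normalizer(apply_normalizer(img, spec), spec)
    assert np.allclose(back, img, atol=1e-5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(img=arrays(np.float32, (6, 6), elements=st.floats(0, 5.0, width=32)),
       clip_max=st.floats(0.5, 10.0))
def test_normalization_bounds_and_roundtrip_property(img, clip_max):
    """For any nonnegative image: output lies in [-1,1], the map is monotone
    in each pixel, and pixels at or below clip_max invert exactly."""
    spec = NormalizationSpec(clip_max=float(clip_max))
    out = apply_normalizer(img, spec)
    assert out.min() >= -1.0 and out.max() <= 1.0
    back = invert_normalizer(out, spec)
    below = img <= clip_max
    assert np.allclose(back[below], img[below], atol=1e-4 * max(clip_max, 1))


def test_normalization_monotone():
    spec = NormalizationSpec(clip_max=3.0)
    xs = np.linspace(0, 3, 50)
    out = apply_normalizer(xs, spec)
    assert np.all(np.diff(out) > 0)


# ------------------------------------------------------------------- flips
def test_flip_involution_and_consistency():
    pair = _pair()
    # force-flip by consuming rng values below 0.5 deterministically

    class AlwaysFlip:
        def random(self):
            return 0.0

    once = augment_flip(pair, AlwaysFlip())
    twice = augment_flip(once, AlwaysFlip())
    assert np.array_equal(twice.pre, pair.pre)
    assert np.array_equal(once.pre, pair.pre[::-1])
    assert np.array_equal(once.mask, pair.mask[::-1])
    # centroid row maps to H-1-row
    r0 = np.argwhere(pair.mask).mean(axis=0)[0]
    r1 = np.argwhere(once.mask).mean(axis=0)[0]
    assert r1 == pytest.approx(pair.mask.shape[0] - 1 - r0)


def test_flip_frequency_monte_carlo():
    pair = _pair()
    rng = np.random.default_rng(5)
    flips = sum(
        not np.array_equal(augment_flip(pair, rng).pre, pair.pre)
        for _ in range(10_000))
    assert flips / 10_000 == pytest.approx(0.5, abs=0.02)


# ------------------------------------------------------------------- crops
def test_crop_window_centered_and_clamped():
    mask = np.zeros((256, 256), dtype=np.uint8)
    mask[128, 128] = 1
    assert crop_window(mask, 64) == (96, 96)
    mask = np.zeros((256, 256), dtype=np.uint8)
    mask[5, 5] = 1
    assert crop_window(mask, 64) == (0, 0)
    mask = np.zeros((256, 256), dtype=np.uint8)
    mask[250, 252] = 1
    assert crop_window(mask, 64) == (192, 192)


def test_crop_patch_shape_and_window_oracle():
    rng = np.random.default_rng(6)
    for _ in range(10):
        mask = np.zeros((64, 64), dtype=np.uint8)
        r, c = rng.integers(0, 64, 2)
        mask[r, c] = 1
        extra = rng.uniform(size=(64, 64)) > 0.97
        mask |= extra.astype(np.uint8)
        patch = crop_tumor_patch(mask, mask, 16)
        assert patch.shape == (16, 16)
        r0, c0 = crop_window(mask, 16)
        assert patch.sum() == mask[r0:r0 + 16, c0:c0 + 16].sum()


def test_crop_empty_mask_errors():
    with pytest.raises(ValueError):
        crop_tumor_patch(np.zeros((8, 8)), np.zeros((8, 8)), 4)


def test_slice_pair_validation():
    with pytest.raises(ValueError):
        SlicePair(pre=np.zeros((4, 4)), ce=np.zeros((4, 4)), mask=np.zeros((4, 4)))
    with pytest.raises(ValueError):
        SlicePair(pre=np.zeros((4, 4)), ce=np.zeros((5, 5)), mask=np.ones((4, 4)))
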