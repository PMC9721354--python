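"""Dual-region metric suite, profiles, error maps and the permutation test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cesynth.evaluation import (
    aggregate_metrics, error_map, intensity_profile, metric_suite, nrmse,
    paired_permutation_test, pearson_cc, psnr, ssim,
)


def _centered_mask(h=64, half=6):
    m = np.zeros((h, h), dtype=np.uint8)
    c = h // 2
    m[c - half:c + half, c - half:c + half] = 1
    return m


def brute_force_ssim_uniform(t, s, win, data_range):
    """Sliding uniform-window SSIM with sample covariance, valid region only."""
    k1, k2 = 0.01, 0.03
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    h, w = t.shape
    vals = []
    r = win // 2
    for i in range(r, h - r):
        for j in range(r, w - r):
            wt = t[i - r:i + r + 1, j - r:j + r + 1].astype(np.float64)
            ws = s[i - r:i + r + 1, j - r:j + r + 1].astype(np.float64)
            mt, ms = wt.mean(), ws.mean()
            vt, vs = wt.var(ddof=1), ws.var(ddof=1)
            cov = ((wt - mt) * (ws - ms)).sum() / (win * win - 1)
            vals.append(((2 * mt * ms + c1) * (2 * cov + c2))
                        / ((mt ** 2 + ms ** 2 + c1) * (vt + vs + c2)))
    return float(np.mean(vals))


def test_identity_metrics():
    rng = np.random.default_rng(0)
    img = rng.uniform(-1, 1, (64, 64)).astype(np.float32)
    rows = metric_suite(img, img.copy(), _centered_mask())
    for row in rows:
        assert row["nrmse"] == 0.0
        assert row["psnr_db"] == np.inf
        assert row["ssim"] == pytest.approx(1.0)
        assert row["cc"] == pytest.approx(1.0)


def test_constant_shift_keeps_cc():
    rng = np.random.default_rng(1)
    img = rng.uniform(-1, 1, (64, 64))
    rows = metric_suite(img, img + 0.2, _centered_mask())
    for row in rows:
        assert row["cc"] == pytest.approx(1.0, abs=1e-6)
        assert row["nrmse"] > 0


def test_hand_computed_4x4_example():
    """Target [[0,0],[1,1]] tiled to 4x4; synthesized off by 0.5 on one quadrant."""
    target = np.tile(np.array([[0.0, 0.0], [1.0, 1.0]]), (2, 2))
    synth = target.copy()
    synth[:2, :2] += 0.5
    # NRMSE: rmse = sqrt(4 * 0.25 / 16) = 0.25; range = 1 -> 25.0
    assert nrmse(target, synth) == pytest.approx(25.0)
    # PSNR: 10 log10(1 / 0.0625)
    assert psnr(target, synth) == pytest.approx(10 * np.log10(1 / 0.0625))
    # CC against direct corrcoef
    assert pearson_cc(target, synth) == pytest.approx(
        np.corrcoef(target.ravel(), synth.ravel())[0, 1])
    # SSIM against an exhaustive sliding-window recomputation
    assert ssim(target, synth) == pytest.approx(
        brute_force_ssim_uniform(target, synth, 3, 1.0), rel=1e-6)


def test_constant_target_flagged_undefined():
    t = np.zeros((32, 32))
    s = np.random.default_rng(2).uniform(size=(32, 32))
    assert np.isnan(nrmse(t, s))
    assert np.isnan(psnr(t, s))
    assert np.isnan(ssim(t, s))
    assert np.isnan(pearson_cc(t, s))


def test_nrmse_normalizer_conventions():
    rng = np.random.default_rng(3)
    t = rng.uniform(1, 2, (16, 16))
    s = t + rng.normal(scale=0.1, size=t.shape)
    rmse = np.sqrt(np.mean((t - s) ** 2))
    assert nrmse(t, s, "range") == pytest.approx(100 * rmse / (t.max() - t.min()))
    assert nrmse(t, s, "mean") == pytest.approx(100 * rmse / t.mean())
    assert nrmse(t, s, "euclidean") == pytest.approx(
        100 * rmse / np.sqrt(np.mean(t ** 2)))
    with pytest.raises(ValueError):
        nrmse(t, s, "bogus")


def test_tumor_crop_consistency_when_centered():
    """On a 64x64 image with a centered tumor, crop metrics equal full metrics."""
    rng = np.random.default_rng(4)
    t = rng.uniform(-1, 1, (64, 64))
    s = np.clip(t + rng.normal(scale=0.1, size=t.shape), -1, 1)
    rows = metric_suite(t, s, _centered_mask(), patch_size=64)
    whole = [r for r in rows if r["region"] == "whole"][0]
    tumor = [r for r in rows if r["region"] == "tumor"][0]
    for k in ("nrmse", "psnr_db", "ssim", "cc"):
        assert whole[k] == pytest.approx(tumor[k])


def test_aggregates_match_brute_force():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(6):
        t = rng.uniform(-1, 1, (64, 64))
        s = np.clip(t + rng.normal(scale=0.2, size=t.shape), -1, 1)
        rows.extend(metric_suite(t, s, _centered_mask(), slice_index=i))
    agg = aggregate_metrics(rows)
    whole_nrmse = [r["nrmse"] for r in rows if r["region"] == "whole"]
    assert agg.loc["whole", ("nrmse", "mean")] == pytest.approx(np.mean(whole_nrmse))
    assert agg.loc["whole", ("nrmse", "std")] == pytest.approx(
        np.std(whole_nrmse, ddof=1))


def test_intensity_profile_column_oracle():
    rng = np.random.default_rng(6)
    img = rng.uniform(size=(32, 32))
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[10:14, 20:25] = 1
    prof = intensity_profile(img, mask)
    col = int(np.floor(np.argwhere(mask)[:, 1].mean() + 0.5))
    assert prof.shape == (32,)
    assert np.array_equal(prof, img[:, col])
    assert np.all(intensity_profile(np.full((8, 8), 3.0), mask[:8, :8] * 0 + 1) == 3.0)
    with pytest.raises(ValueError):
        intensity_profile(img, np.zeros_like(mask))


def test_error_map_linearity_and_argmax():
    rng = np.random.default_rng(7)
    t = rng.uniform(size=(16, 16))
    s = rng.uniform(size=(16, 16))
    e = error_map(t, s)
    assert np.allclose(e, t - s)
    assert e.mean() == pytest.approx(t.mean() - s.mean())
    assert np.unravel_index(np.abs(e).argmax(), e.shape) == max(
        itertools.product(range(16), range(16)), key=lambda rc: abs(t[rc] - s[rc]))
    assert not error_map(t, t).any()


# ------------------------------------------------------------- permutation
def test_permutation_p_is_one_under_exact_null():
    a = np.arange(10.0)
    assert paired_permutation_test(a, a.copy(), n_perm=500) == 1.0


def test_permutation_matches_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    a = rng.normal(size=10)
    b = a + rng.normal(scale=0.8, size=10)
    d = a - b
    t_obs = abs(d.mean())
    count = sum(
        abs((d * np.array(signs)).mean()) >= t_obs - 1e-12
        for signs in itertools.product((-1.0, 1.0), repeat=10))
    exact = count / 2 ** 10
    mc = paired_permutation_test(a, b, n_perm=10_000, seed=0)
    assert mc == pytest.approx(exact, abs=0.02)


def test_permutation_p_uniform_under_simulated_null():
    rng = np.random.default_rng(9)
    ps = []
    for rep in range(500):
        d = rng.normal(size=20)
        ps.append(paired_permutation_test(d, np.zeros(20), n_perm=200, seed=rep))
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_permutation_input_validation():
    with pytest.raises(ValueError):
        paired_permutation_test(np.ones(5), np.ones(4))
    with pytest.raises(ValueError):
        paired_permutation_test(np.ones(5), np.ones(5), n_perm=50)
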