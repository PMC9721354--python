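"""Dual-region synthesis evaluation: NRMSE, PSNR, SSIM, Pearson CC.

Each target/synthesized slice is scored twice: on the full field of view
(which deliberately includes the air background) and on a tumor-centered
crop (default 64x64).  NRMSE is reported as 100 * RMSE / normalizer with the
normalizer convention configurable (target dynamic range by default, or the
target mean, or its root-mean-square); PSNR uses the target's own dynamic
range unless a fixed range is given (use 2.0 for [-1,1] images).  SSIM uses
the standard 11x11 Gaussian window (sigma 1.5) when the image is large
enough, otherwise the largest odd uniform window that fits.  Metrics that
are undefined (constant target, zero variance) are reported as NaN rather
than silently zero; a perfect reconstruction reports PSNR = +inf.

Methods are compared per slice with a paired sign-flip permutation test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .preprocessing import crop_tumor_patch

__all__ = [
    "nrmse", "psnr", "ssim", "pearson_cc", "metric_suite", "aggregate_metrics",
    "intensity_profile", "error_map", "paired_permutation_test",
]


def _range(target: np.ndarray) -> float:
    return float(target.max() - target.min())


def nrmse(target, synthesized, normalizer: str = "range") -> float:
    """100 * RMSE / normalizer; NaN when the normalizer degenerates to 0."""
    t = np.asarray(target, dtype=np.float64)
    s = np.asarray(synthesized, dtype=np.float64)
    rmse = float(np.sqrt(np.mean((t - s) ** 2)))
    if normalizer == "range":
        denom = _range(t)
    elif normalizer == "mean":
        denom = float(np.abs(t.mean()))
    elif normalizer == "euclidean":
        denom = float(np.sqrt(np.mean(t ** 2)))
    else:
        raise ValueError(f"unknown NRMSE normalizer {normalizer!r}")
    if denom == 0:
        return float("nan")
    return 100.0 * rmse / denom


def psnr(target, synthesized, data_range: float | None = None) -> float:
    """10 log10(R^2 / MSE); +inf for identical images, NaN for zero range."""
    t = np.asarray(target, dtype=np.float64)
    s = np.asarray(synthesized, dtype=np.float64)
    r = _range(t) if data_range is None else float(data_range)
    if r == 0:
        return float("nan")
    mse = float(np.mean((t - s) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(r * r / mse)


def ssim(target, synthesized, data_range: float | None = None) -> float:
    """Structural similarity; Gaussian 11x11 window when the image allows."""
    t = np.asarray(target, dtype=np.float64)
    s = np.asarray(synthesized, dtype=np.float64)
    r = _range(t) if data_range is None else float(data_range)
    if r == 0:
        return float("nan")
    if min(t.shape) >= 11:
        return float(structural_similarity(
            t, s, data_range=r, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False))
    win = min(t.shape)
    win = win if win % 2 else win - 1
    return float(structural_similarity(t, s, data_range=r, win_size=win))


def pearson_cc(target, synthesized) -> float:
    """Pearson correlation over pixels; NaN for constant inputs."""
    t = np.asarray(target, dtype=np.float64).ravel()
    s = np.asarray(synthesized, dtype=np.float64).ravel()
    if t.std() == 0 or s.std() == 0:
        return float("nan")
    return float(np.corrcoef(t, s)[0, 1])


def metric_suite(target, synthesized, mask, subject: str = "", slice_index: int = 0,
                 patch_size: int = 64, nrmse_normalizer: str = "range",
                 psnr_range: float | None = None, ssim_range: float | None = None,
                 ) -> list[dict]:
    """Whole-FOV and tumor-crop metric rows for one slice pair."""
    t = np.asarray(target)
    s = np.asarray(synthesized)
    if t.shape != s.shape:
        raise ValueError("target and synthesized must share one shape")
    if not np.asarray(mask).any():
        raise ValueError("tumor metrics require a nonempty mask")
    rows = []
    for region, (tt, ss) in (
            ("whole", (t, s)),
            ("tumor", (crop_tumor_patch(t, mask, patch_size),
                       crop_tumor_patch(s, mask, patch_size)))):
        rows.append({
            "subject": subject, "slice": slice_index, "region": region,
            "nrmse": nrmse(tt, ss, nrmse_normalizer),
            "psnr_db": psnr(tt, ss, psnr_range),
            "ssim": ssim(tt, ss, ssim_range),
            "cc": pearson_cc(tt, ss),
        })
    return rows


def aggregate_metrics(rows) -> pd.DataFrame:
    """Mean and standard deviation per region and metric."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    return (df.groupby("region")[["nrmse", "psnr_db", "ssim", "cc"]]
              .agg(["mean", "std"]))


def intensity_profile(img, mask) -> np.ndarray:
    """The image column through the tumor centroid (full image height)."""
    img = np.asarray(img)
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("intensity_profile requires a nonempty mask")
    _, c = np.argwhere(mask).mean(axis=0)
    col = int(np.floor(float(c) + 0.5))
    return img[:, col].copy()


def error_map(target, synthesized) -> np.ndarray:
    """Signed difference target - synthesized."""
    t = np.asarray(target)
    s = np.asarray(synthesized)
    if t.shape != s.shape:
        raise ValueError("target and synthesized must share one shape")
    return t - s


def paired_permutation_test(metric_a, metric_b, n_perm: int = 10_000,
                            seed: int = 0) -> float:
    """Two-sided sign-flip permutation p-value for the mean paired difference."""
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired vectors")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    d = a - b
    t_obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, d.size))
    t_perm = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(t_perm >= t_obs)) / (1 + n_perm))
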