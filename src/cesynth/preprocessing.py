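"""Volume-to-slice preprocessing for paired pre-/post-contrast MRI.

Pipeline: resample volumes to isotropic spacing (cubic B-spline for images,
nearest neighbour for masks), keep only axial slices intersecting the tumor
mask, resize to the working resolution (bilinear / nearest), and normalize
both phases jointly.  Normalization deliberately shares one scale across
phases: intensities are clipped at the maximum of the contrast-enhanced
images over the *training* set and mapped linearly onto [-1, 1], so that the
enhancement signal between phases survives (a per-image standardization would
erase it).  Validation and test data reuse the training specification; an
external cohort may fit its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from skimage.transform import resize as _sk_resize

from .phantoms import Volume

__all__ = [
    "SlicePair", "NormalizationSpec", "resample_isotropic", "select_tumor_slices",
    "fit_normalizer", "apply_normalizer", "invert_normalizer", "augment_flip",
    "crop_window", "crop_tumor_patch", "make_slice_pairs",
]


@dataclass
class SlicePair:
    """One training/evaluation unit: paired normalized slices plus mask."""

    pre: np.ndarray
    ce: np.ndarray
    mask: np.ndarray
    subject_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        if not (self.pre.shape == self.ce.shape == self.mask.shape):
            raise ValueError("pre, ce and mask must share one shape")
        if not self.mask.any():
            raise ValueError("SlicePair requires a nonempty tumor mask")


@dataclass(frozen=True)
class NormalizationSpec:
    """Global intensity scale: the ceT1 maximum over the training slices."""

    clip_max: float

    def __post_init__(self):
        if self.clip_max <= 0:
            raise ValueError("clip_max must be positive")


def resample_isotropic(v: Volume, target_spacing: float = 1.0) -> Volume:
    """Resample a volume to isotropic spacing.

    Cubic B-spline interpolation for image volumes, nearest neighbour for
    masks (so labels stay binary).
    """
    if v.spacing is None or any(s <= 0 for s in v.spacing):
        raise ValueError("volume spacing must be known and positive")
    img = sitk.GetImageFromArray(np.asarray(v.data, dtype=np.float32))
    # SimpleITK spacing is (x, y, z); our array axes are (z, y, x)
    img.SetSpacing(tuple(float(s) for s in v.spacing[::-1]))
    old_size = np.array(img.GetSize(), dtype=float)
    old_sp = np.array(img.GetSpacing())
    new_size = np.round(old_size * old_sp / target_spacing).astype(int)
    interp = sitk.sitkNearestNeighbor if v.modality == "mask" else sitk.sitkBSpline
    res = sitk.Resample(
        img, [int(s) for s in new_size], sitk.Transform(), interp,
        img.GetOrigin(), (target_spacing,) * 3, img.GetDirection(), 0.0,
        sitk.sitkFloat32,
    )
    data = sitk.GetArrayFromImage(res)
    if v.modality == "mask":
        data = (data > 0.5).astype(np.uint8)
    return Volume(data, (target_spacing,) * 3, v.modality)


def select_tumor_slices(mask) -> list[int]:
    """Ascending axial indices of slices with at least one mask pixel."""
    data = mask.data if isinstance(mask, Volume) else np.asarray(mask)
    return [int(i) for i in range(data.shape[0]) if data[i].any()]


def fit_normalizer(training_ce_slices) -> NormalizationSpec:
    """clip_max = global maximum over the provided ceT1 training slices."""
    slices = list(training_ce_slices)
    if not slices:
        raise ValueError("fit_normalizer requires at least one slice")
    m = max(float(np.max(s)) for s in slices)
    return NormalizationSpec(clip_max=m)


def apply_normalizer(img: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    """Clip at ``clip_max`` and map linearly onto [-1, 1]."""
    img = np.asarray(img, dtype=np.float32)
    if (img < 0).any():
        raise ValueError("raw MRI magnitudes must be nonnegative")
    return (2.0 * np.minimum(img, spec.clip_max) / spec.clip_max - 1.0).astype(np.float32)


def invert_normalizer(img: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    """Map a [-1, 1] image back to intensity units (exact below clip_max)."""
    return ((np.asarray(img, dtype=np.float32) + 1.0) * 0.5 * spec.clip_max).astype(np.float32)


def augment_flip(pair: SlicePair, rng: np.random.Generator) -> SlicePair:
    """With probability 0.5, flip pre/ce/mask up-down together."""
    if rng.random() < 0.5:
        return SlicePair(pre=pair.pre[::-1].copy(), ce=pair.ce[::-1].copy(),
                         mask=pair.mask[::-1].copy(),
                         subject_id=pair.subject_id, slice_index=pair.slice_index)
    return pair


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def crop_window(mask: np.ndarray, size: int) -> tuple[int, int]:
    """Top-left corner of the size x size window centered on the mask centroid.

    The centroid is the arithmetic mean of mask pixel coordinates rounded
    half-up; the window is clamped inside the image so no padding is needed.
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("crop_window requires a nonempty mask")
    h, w = mask.shape
    if size > h or size > w:
        raise ValueError("patch size exceeds image size")
    r, c = np.argwhere(mask).mean(axis=0)
    r0 = min(max(_round_half_up(float(r)) - size // 2, 0), h - size)
    c0 = min(max(_round_half_up(float(c)) - size // 2, 0), w - size)
    return r0, c0


def crop_tumor_patch(img: np.ndarray, mask: np.ndarray, size: int = 64) -> np.ndarray:
    """Tumor-centered size x size patch of ``img`` (window defined by ``mask``)."""
    r0, c0 = crop_window(mask, size)
    return np.asarray(img)[r0:r0 + size, c0:c0 + size]


def _resize_slice(sl: np.ndarray, size: int, is_mask: bool) -> np.ndarray:
    if sl.shape == (size, size):
        return sl.astype(np.uint8 if is_mask else np.float32)
    out = _sk_resize(sl.astype(np.float32), (size, size),
                     order=0 if is_mask else 1, preserve_range=True,
                     anti_aliasing=False)
    return (out > 0.5).astype(np.uint8) if is_mask else out.astype(np.float32)


def make_slice_pairs(pre: Volume, ce: Volume, mask: Volume,
                     spec: NormalizationSpec, subject_id: str,
                     image_size: int = 256) -> list[SlicePair]:
    """Extract normalized tumor-slice pairs from one subject's volumes."""
    if pre.data.shape != ce.data.shape or pre.data.shape != mask.data.shape:
        raise ValueError("pre, ce and mask volumes must share one shape")
    pairs = []
    for idx in select_tumor_slices(mask):
        m = _resize_slice(mask.data[idx], image_size, is_mask=True)
        if not m.any():  # tumor lost by downsampling: skip
            continue
        pairs.append(SlicePair(
            pre=apply_normalizer(np.clip(_resize_slice(pre.data[idx], image_size, False), 0, None), spec),
            ce=apply_normalizer(np.clip(_resize_slice(ce.data[idx], image_size, False), 0, None), spec),
            mask=m, subject_id=subject_id, slice_index=idx))
    return pairs
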