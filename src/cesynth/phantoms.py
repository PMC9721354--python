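"""Paired pre-/post-contrast breast MRI phantoms with tumor masks.

The generator emulates the statistical structure the synthesis model assumes:
a breast region (half-ellipse over a chest-wall band) against an air
background, a single ellipsoidal tumor with internal texture and strong
contrast enhancement, mild diffuse enhancement of normal tissue, and additive
acquisition noise.  The enhanced volume is constructed as

    ceT1 = enhancement_field * preT1 + noise,

where the field equals ``tumor_enhancement_ratio`` inside the tumor,
``background_enhancement_ratio`` in breast tissue, and 1 in air.  The tumor
border is smoothed as an outward ramp (the binary mask region carries the
full tumor ratio), so the empirical tumor contrast equals the nominal ratio
exactly at zero noise.  Identical parameters and seed give bit-identical
volumes.

This is a geometric phantom, not a pharmacokinetic (Tofts-type) enhancement
model; there are no bias fields or multi-coil artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["PhantomParams", "Volume", "generate_subject", "generate_dataset",
           "write_dataset", "read_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the phantom simulator (lengths in pixels at 1 mm)."""

    image_size: int = 256
    n_subjects: int = 4
    slices_per_subject: int = 24
    tumor_radius_range: tuple[float, float] = (10.0, 24.0)
    tumor_enhancement_ratio: float = 2.2
    background_enhancement_ratio: float = 1.15
    texture_scale: float = 8.0
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> "PhantomParams":
        if self.image_size <= 0 or self.n_subjects <= 0 or self.slices_per_subject <= 0:
            raise ValueError("sizes and counts must be positive")
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi:
            raise ValueError("tumor_radius_range must be positive and ascending")
        if self.background_enhancement_ratio < 1.0 or self.tumor_enhancement_ratio < 1.0:
            raise ValueError("enhancement ratios must be >= 1")
        if self.tumor_enhancement_ratio < self.background_enhancement_ratio:
            raise ValueError("tumor enhancement must be >= background enhancement")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        return self

    @classmethod
    def tiny(cls, **overrides) -> "PhantomParams":
        """Desk-scale profile: 64x64 slices with proportionally smaller tumors."""
        base = cls(image_size=64, slices_per_subject=12,
                   tumor_radius_range=(5.0, 8.0), texture_scale=4.0)
        return replace(base, **overrides)


@dataclass
class Volume:
    """A 3-D scalar volume (slice, row, column) with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "preT1"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D")
        if self.modality == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask volumes must contain only {0, 1}")


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _textured_noise(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Zero-mean, unit-std band-limited noise (smoothed white noise)."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=scale)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _breast_region(h: int, w: int) -> np.ndarray:
    """Half-ellipse breast over a chest-wall band; True where tissue."""
    rows, cols = np.mgrid[0:h, 0:w]
    base_row = 0.72 * h
    ellipse = (((rows - base_row) / (0.58 * h)) ** 2
               + ((cols - 0.5 * w) / (0.42 * w)) ** 2) <= 1.0
    breast = ellipse & (rows <= base_row)
    chest = (rows > base_row) & (rows <= 0.86 * h) & (cols > 0.08 * w) & (cols < 0.92 * w)
    return breast | chest


def generate_subject(params: PhantomParams, subject_index: int,
                     ) -> tuple[Volume, Volume, Volume]:
    """Generate one subject's paired (preT1, ceT1, mask) volumes."""
    params.validate()
    rng = np.random.default_rng([params.seed, subject_index])
    d, h, w = params.slices_per_subject, params.image_size, params.image_size

    breast2d = _breast_region(h, w)
    breast = np.broadcast_to(breast2d, (d, h, w)).astype(np.float32)

    # tissue with band-limited texture; air near zero
    tex = _textured_noise(rng, (d, h, w), params.texture_scale)
    tissue = 0.45 + 0.12 * np.clip(tex, -2.5, 2.5)
    pre = breast * tissue + (1.0 - breast) * 0.01

    # tumor: ellipsoid fitting inside the breast with a safety margin
    border_px = 2.0
    r_mean = float(rng.uniform(*params.tumor_radius_range))
    rz = max(min(r_mean * 0.6, d / 2.0 - 1.5), 1.0)
    rr = rc = r_mean
    # erode breast by radius + border so the smoothed tumor stays inside
    margin = int(np.ceil(r_mean + border_px)) + 1
    safe = ndimage.binary_erosion(breast2d, iterations=margin)
    if not safe.any():
        raise ValueError("tumor does not fit inside the breast region; "
                         "reduce tumor_radius_range or increase image_size")
    centers = np.argwhere(safe)
    cr, cc = centers[rng.integers(len(centers))]
    cz = d / 2.0 + float(rng.uniform(-d / 8.0, d / 8.0))

    zz, yy, xx = np.mgrid[0:d, 0:h, 0:w].astype(np.float32)
    rho = np.sqrt(((zz - cz) / rz) ** 2 + ((yy - cr) / rr) ** 2 + ((xx - cc) / rc) ** 2)
    mask = (rho <= 1.0).astype(np.uint8)
    # outward ramp: full weight inside the mask, smooth falloff over ~2 px
    weight = 1.0 - _smoothstep((rho - 1.0) * r_mean / border_px)

    # internal tumor texture lives in preT1 and is shared with ceT1
    ttex = _textured_noise(rng, (d, h, w), max(params.texture_scale / 2.0, 1.0))
    pre = pre * np.clip(1.0 + 0.25 * ttex * weight, 0.6, 1.4)

    noise_pre = rng.standard_normal((d, h, w)) * params.noise_sigma
    pre = np.clip(pre + noise_pre, 0.0, None).astype(np.float32)

    fld = (1.0 + (params.background_enhancement_ratio - 1.0) * breast
           + (params.tumor_enhancement_ratio - params.background_enhancement_ratio)
           * weight)
    noise_ce = rng.standard_normal((d, h, w)) * params.noise_sigma
    ce = np.clip(fld * pre + noise_ce, 0.0, None).astype(np.float32)

    if not mask.any():
        raise RuntimeError("phantom tumor mask is empty (internal error)")
    sp = (1.0, 1.0, 1.0)
    return (Volume(pre, sp, "preT1"), Volume(ce, sp, "ceT1"), Volume(mask, sp, "mask"))


def generate_dataset(params: PhantomParams) -> list[tuple[Volume, Volume, Volume]]:
    return [generate_subject(params, i) for i in range(params.n_subjects)]


def _slice_centroids(mask: np.ndarray) -> dict[int, list[float]]:
    out = {}
    for i in range(mask.shape[0]):
        sl = mask[i]
        if sl.any():
            r, c = np.argwhere(sl).mean(axis=0)
            out[int(i)] = [float(r), float(c)]
    return out


def write_dataset(subjects, directory) -> dict:
    """Write NIfTI volumes plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": []}
    for idx, (pre, ce, mask) in enumerate(subjects):
        sid = f"subject_{idx:03d}"
        entry = {"id": sid, "paths": {}, "tumor_centroids": _slice_centroids(mask.data)}
        for vol, name in ((pre, "preT1"), (ce, "ceT1"), (mask, "mask")):
            path = directory / f"{sid}_{name}.nii.gz"
            affine = np.diag(list(vol.spacing) + [1.0])
            try:
                nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), path)
            except OSError as exc:
                raise OSError(f"failed to write {path}: {exc}") from exc
            entry["paths"][name] = path.name
        manifest["subjects"].append(entry)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_dataset(directory) -> list[tuple[Volume, Volume, Volume]]:
    """Load a written dataset back into memory (inverse of :func:`write_dataset`)."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    subjects = []
    for entry in manifest["subjects"]:
        vols = []
        for name in ("preT1", "ceT1", "mask"):
            img = nib.load(directory / entry["paths"][name])
            spacing = tuple(float(s) for s in np.diag(img.affine)[:3])
            data = np.asarray(img.dataobj, dtype=np.float32)
            if name == "mask":
                data = data.astype(np.uint8)
            vols.append(Volume(data, spacing, name))
        subjects.append(tuple(vols))
    return subjects
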