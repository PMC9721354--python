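"""Sobel edge maps used as discriminator input channels and in edge losses.

The soft map is the sum of the absolute horizontal and vertical Sobel
responses, normalized by its per-image maximum so that a fixed binarization
threshold (0.4) stays meaningful across slices of differing dynamic range.
Borders are reflect-padded.  Two parallel implementations share these
conventions exactly: a plain-numpy one for evaluation and I/O, and a
differentiable one used inside generator losses, where the binarized map is
passed to discriminators with a straight-through (identity) gradient because
hard thresholding has zero gradient almost everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn.autodiff import Tensor, conv2d

__all__ = ["EdgeMap", "compute_soft_edges", "binarize", "soft_edges_t", "binarize_st"]

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float32)
SOBEL_Y = SOBEL_X.T.copy()

DEFAULT_THRESHOLD = 0.4


def compute_soft_edges(img: np.ndarray) -> np.ndarray:
    """Soft edge map in [0, 1] of a 2-D image (zero map for constant input)."""
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("compute_soft_edges expects a 2-D image")
    # scipy's "mirror" boundary equals reflect padding without edge repetition
    gx = ndimage.correlate(img, SOBEL_X, mode="mirror")
    gy = ndimage.correlate(img, SOBEL_Y, mode="mirror")
    mag = np.abs(gx) + np.abs(gy)
    m = mag.max()
    if m <= 0:
        return np.zeros_like(mag)
    return mag / m


def binarize(soft: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary edge map: 1 exactly where ``soft >= threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(soft) >= threshold).astype(np.float32)


@dataclass
class EdgeMap:
    """Soft ([0,1]) and binarized ({0,1}) Sobel edge representation."""

    soft: np.ndarray
    binary: np.ndarray = field(default=None)
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if self.binary is None:
            self.binary = binarize(self.soft, self.threshold)

    @classmethod
    def from_image(cls, img: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> "EdgeMap":
        return cls(soft=compute_soft_edges(img), threshold=threshold)


# ----------------------------------------------------------- differentiable
_KX = Tensor(SOBEL_X.reshape(1, 1, 3, 3))
_KY = Tensor(SOBEL_Y.reshape(1, 1, 3, 3))


def soft_edges_t(x: Tensor) -> Tensor:
    """Differentiable soft edge maps for an (N,1,H,W) tensor.

    The per-image normalizing maximum is treated as a constant in the backward
    pass; its subgradient is supported on a single pixel and only adds noise.
    """
    gx = conv2d(x, _KX, pad=1, pad_mode="reflect")
    gy = conv2d(x, _KY, pad=1, pad_mode="reflect")
    mag = gx.abs() + gy.abs()
    m = mag.data.max(axis=(1, 2, 3), keepdims=True)
    inv = np.where(m > 0, 1.0 / np.maximum(m, 1e-30), 0.0).astype(np.float32)
    return mag * Tensor(inv)


def binarize_st(soft: Tensor, threshold: float = DEFAULT_THRESHOLD) -> Tensor:
    """Binarize with a straight-through gradient (forward hard, backward identity)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    out_data = (soft.data >= threshold).astype(np.float32)

    def backward(g):
        if soft.requires_grad:
            soft._accum(g)

    return soft._make(out_data, (soft,), backward)
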