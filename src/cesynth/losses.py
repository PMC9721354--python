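"""Adversarial, segmentation and composite L1 objectives.

Discriminators are trained with the hinge loss; the generator's adversarial
term is the non-saturating hinge companion, -E[D(fake)].  The segmentor
minimizes binary cross-entropy plus Dice loss on the target enhanced image.
The generator additionally minimizes a seven-term L1 objective: whole-image
intensity and edge similarity, tumor-patch intensity and edge similarity,
segmentation-masked intensity similarity (the segmentor acting as a fixed
soft mask), and feature matching against the penultimate maps of both
discriminators.  Tumor-focused terms are ramped in by a curriculum weight
lambda_curr(epoch) = min(5*epoch, 100), so early training shapes the whole
breast and later training concentrates on the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edges import binarize_st, soft_edges_t
from .nn import Tensor, cat, frozen
from .preprocessing import crop_window

__all__ = [
    "LossWeights", "hinge_d_loss", "hinge_g_loss", "seg_loss",
    "curriculum_lambda", "l1", "generator_l1_loss", "generator_objective",
    "extract_patches", "discriminator_input",
]


@dataclass(frozen=True)
class LossWeights:
    """Loss weights; defaults are the tuned values of the reference model."""

    lambda_global: float = 300.0
    lambda_edge: float = 20.0
    lambda_curr_cap: float = 100.0
    lambda_curr_slope: float = 5.0
    lambda_adv: float = 5.0
    lambda_fm: float = 1.0

    def __post_init__(self):
        for name in ("lambda_global", "lambda_edge", "lambda_curr_cap",
                     "lambda_curr_slope", "lambda_adv", "lambda_fm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def hinge_d_loss(real_scores, fake_scores) -> Tensor:
    """mean max(0, 1 - real) + mean max(0, 1 + fake).

    Algebraically equal to the -E[min(0, -1 + D(real))] - E[min(0, -1 - D(fake))]
    formulation of the discriminator hinge objective.
    """
    real, fake = _as_tensor(real_scores), _as_tensor(fake_scores)
    if real.shape != fake.shape:
        raise ValueError("real and fake score grids must share one shape")
    return (1.0 - real).relu().mean() + (1.0 + fake).relu().mean()


def hinge_g_loss(fake_scores) -> Tensor:
    """Non-saturating generator companion of the hinge loss: -E[D(fake)]."""
    return -(_as_tensor(fake_scores).mean())


def seg_loss(pred_prob, label, eps: float = 1e-6) -> Tensor:
    """Binary cross-entropy plus Dice loss for a probability map."""
    p, l = _as_tensor(pred_prob), _as_tensor(label)
    if p.shape != l.shape:
        raise ValueError("prediction and label must share one shape")
    pc = p.clip(1e-7, 1.0 - 1e-7)
    bce = -((l * pc.log() + (1.0 - l) * (1.0 - pc).log()).mean())
    dice = 1.0 - (2.0 * (p * l).sum() + eps) / (p.sum() + l.sum() + eps)
    return bce + dice


def curriculum_lambda(epoch: int, slope: float = 5.0, cap: float = 100.0) -> float:
    """min(slope * epoch, cap); the tumor-term curriculum weight."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return float(min(slope * epoch, cap))


def l1(a, b) -> Tensor:
    """Mean absolute difference (the expectation form of the L1 norm)."""
    return (_as_tensor(a) - _as_tensor(b)).abs().mean()


def extract_patches(t: Tensor, windows: list[tuple[int, int]], size: int) -> Tensor:
    """Per-sample tumor-centered crops of an (N,C,H,W) tensor."""
    crops = [t[i:i + 1, :, r0:r0 + size, c0:c0 + size]
             for i, (r0, c0) in enumerate(windows)]
    return cat(crops, axis=0)


def discriminator_input(cond: Tensor, cand: Tensor, use_edge: bool = True,
                        cond_soft: Tensor | None = None,
                        cand_soft: Tensor | None = None) -> Tensor:
    """4-channel critic input [cond, cond_edge, cand, cand_edge].

    Edge channels are the binarized soft maps (straight-through gradients);
    precomputed soft maps may be supplied to avoid recomputation.  With
    ``use_edge`` disabled they are replaced by zero maps so the critic keeps
    its 4-channel contract under ablation.
    """
    if use_edge:
        ce_edge = binarize_st(cond_soft if cond_soft is not None else soft_edges_t(cond))
        ca_edge = binarize_st(cand_soft if cand_soft is not None else soft_edges_t(cand))
    else:
        ce_edge = Tensor(np.zeros(cond.shape, dtype=np.float32))
        ca_edge = Tensor(np.zeros(cand.shape, dtype=np.float32))
    return cat([cond, ce_edge, cand, ca_edge], axis=1)


def generator_l1_loss(x, y, gx, masks, S, GD, LD, weights: LossWeights,
                      epoch: int, patch_size: int = 64, use_edge: bool = True,
                      use_ld: bool = True, use_segmentor: bool = True,
                      x_edge: Tensor | None = None, y_edge: Tensor | None = None,
                      gx_edge: Tensor | None = None,
                      gd_feats: tuple[Tensor, Tensor] | None = None,
                      ld_feats: tuple[Tensor, Tensor] | None = None,
                      ) -> tuple[Tensor, dict]:
    """The seven-term weighted L1 objective of the generator.

    ``x``, ``y`` are the pre-contrast input and enhanced target, ``gx`` the
    synthesized image (all (N,1,H,W) tensors in [-1,1]); ``masks`` the binary
    tumor masks (N,H,W).  ``S``, ``GD``, ``LD`` participate as fixed feature
    extractors: their parameters are frozen so only the generator receives
    gradients.  Tumor-region terms act on tumor-centered crops of the images
    and of the full-image edge maps.  Precomputed soft edge maps and
    discriminator penultimate features (real, fake) may be passed to avoid
    recomputation inside a training step.  Returns (total, report); the
    report maps term names to floats and contains only the terms of enabled
    components.
    """
    x, y, gx = _as_tensor(x), _as_tensor(y), _as_tensor(gx)
    masks = np.asarray(masks)
    if masks.ndim != 3 or not all(masks[i].any() for i in range(masks.shape[0])):
        raise ValueError("every sample needs a nonempty tumor mask")
    lam_curr = curriculum_lambda(epoch, weights.lambda_curr_slope, weights.lambda_curr_cap)

    windows = [crop_window(masks[i], patch_size) for i in range(masks.shape[0])]
    y_p = extract_patches(y, windows, patch_size)
    gx_p = extract_patches(gx, windows, patch_size)

    need_d_forward = gd_feats is None or (use_ld and ld_feats is None)
    terms: dict[str, Tensor] = {}
    terms["l1_global"] = weights.lambda_global * l1(y, gx)
    if use_edge:
        if y_edge is None:
            y_edge = soft_edges_t(y)
        if gx_edge is None:
            gx_edge = soft_edges_t(gx)
        if x_edge is None and need_d_forward:
            x_edge = soft_edges_t(x)
        terms["l1_edge"] = weights.lambda_edge * l1(y_edge, gx_edge)
    terms["l1_tumor"] = lam_curr * l1(y_p, gx_p)
    if use_segmentor:
        with frozen(S):
            sy = S(y)
            sgx = S(gx)
        terms["l1_seg_masked"] = lam_curr * l1(sy * y, sgx * gx)
    if use_edge:
        terms["l1_tumor_edge"] = weights.lambda_edge * l1(
            extract_patches(y_edge, windows, patch_size),
            extract_patches(gx_edge, windows, patch_size))
    if gd_feats is None:
        with frozen(GD):
            _, feat_real = GD(discriminator_input(x, y, use_edge, cond_soft=x_edge,
                                                  cand_soft=y_edge))
            _, feat_fake = GD(discriminator_input(x, gx, use_edge, cond_soft=x_edge,
                                                  cand_soft=gx_edge))
    else:
        feat_real, feat_fake = gd_feats
    terms["fm_global"] = weights.lambda_fm * l1(feat_real.detach(), feat_fake)
    if use_ld:
        if ld_feats is None:
            x_p = extract_patches(x, windows, patch_size)
            xe_p = extract_patches(x_edge, windows, patch_size) if use_edge else None
            ye_p = extract_patches(y_edge, windows, patch_size) if use_edge else None
            ge_p = extract_patches(gx_edge, windows, patch_size) if use_edge else None
            with frozen(LD):
                _, lfeat_real = LD(discriminator_input(x_p, y_p, use_edge,
                                                       cond_soft=xe_p, cand_soft=ye_p))
                _, lfeat_fake = LD(discriminator_input(x_p, gx_p, use_edge,
                                                       cond_soft=xe_p, cand_soft=ge_p))
        else:
            lfeat_real, lfeat_fake = ld_feats
        terms["fm_local"] = weights.lambda_fm * l1(lfeat_real.detach(), lfeat_fake)

    total = None
    for t in terms.values():
        total = t if total is None else total + t
    report = {name: float(t.data) for name, t in terms.items()}
    report["lambda_curr"] = lam_curr
    return total, report


def generator_objective(adv_losses: list[Tensor], l1_total: Tensor,
                        weights: LossWeights) -> Tensor:
    """lambda_adv * (sum of generator hinge terms) + the L1 objective."""
    total = l1_total
    for adv in adv_losses:
        total = total + weights.lambda_adv * adv
    return total
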