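"""Adversarial training of the four networks.

Per step: (a) both discriminators take a hinge-loss update on real vs
synthesized pairs, (b) the segmentor takes a BCE+Dice update on the target
enhanced image only, (c) the generator takes one update on the composite
objective (hinge adversarial terms plus the seven-term L1 loss with the
epoch-indexed curriculum weight, epochs counted from 1).  Ablation flags
remove components (and their loss terms) without changing any remaining
tensor shape.  All randomness flows from the config seed, so identical
config + seed reproduce identical parameters bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .edges import binarize_st, compute_soft_edges, soft_edges_t
from .losses import (
    LossWeights, extract_patches, generator_l1_loss,
    generator_objective, hinge_d_loss, hinge_g_loss, seg_loss,
)
from .networks import (
    DiscriminatorConfig, GeneratorConfig, NetworkBundle, SegmentorConfig,
    build_discriminator, build_generator, build_segmentor,
)
from .nn import Adam, Tensor, cat, frozen
from .preprocessing import (
    NormalizationSpec, SlicePair, crop_tumor_patch, crop_window, fit_normalizer,
)
from .phantoms import PhantomParams

__all__ = [
    "TrainConfig", "TrainResult", "build_bundle", "train", "synthesize",
    "save_checkpoint", "load_checkpoint", "phantom_slice_pairs",
    "convergence_study", "tumor_patch_l1",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    lr_s: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    use_sn: bool = True
    use_ld: bool = True
    use_edge: bool = True
    use_segmentor: bool = True
    augment: bool = True
    image_size: int = 256
    base_width: int = 64
    d_base_width: int = 64
    s_depth: int = 5
    patch_size: int = 64
    weights: LossWeights = field(default_factory=LossWeights)
    checkpoint_dir: str | None = None

    def validate(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        return self

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        """Desk-scale profile: 64x64 images, base width 8, 16x16 patches."""
        base = cls(image_size=64, base_width=8, d_base_width=8, patch_size=16)
        return replace(base, **overrides)


@dataclass
class TrainResult:
    bundle: NetworkBundle
    log: pd.DataFrame
    config: TrainConfig
    epoch1_g_state: dict
    normalizer: NormalizationSpec | None = None


def build_bundle(config: TrainConfig, rng: np.random.Generator | None = None) -> NetworkBundle:
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    g = build_generator(GeneratorConfig(
        base_width=config.base_width, image_size=config.image_size,
        use_spectral_norm=config.use_sn), rng)
    gd = build_discriminator(DiscriminatorConfig(
        n_layers=4, base_width=config.d_base_width, input_size=config.image_size,
        use_spectral_norm=config.use_sn), rng)
    ld = build_discriminator(DiscriminatorConfig(
        n_layers=3, base_width=config.d_base_width, input_size=config.patch_size,
        use_spectral_norm=config.use_sn), rng)
    s = build_segmentor(SegmentorConfig(
        depth=config.s_depth, base_width=config.base_width,
        image_size=config.image_size), rng)
    return NetworkBundle(G=g, GD=gd, LD=ld, S=s)


def _stack(pairs: list[SlicePair]):
    x = np.stack([p.pre for p in pairs])[:, None].astype(np.float32)
    y = np.stack([p.ce for p in pairs])[:, None].astype(np.float32)
    m = np.stack([p.mask for p in pairs]).astype(np.float32)
    return x, y, m


def train(config: TrainConfig, pairs: list[SlicePair],
          normalizer: NormalizationSpec | None = None) -> TrainResult:
    """Run the full adversarial training loop on normalized slice pairs."""
    config.validate()
    if not pairs:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    bundle = build_bundle(config, rng)
    G, GD, LD, S = bundle.G, bundle.GD, bundle.LD, bundle.S

    opt_g = Adam(G.parameters(), config.lr_g, config.betas)
    opt_d = Adam(GD.parameters() + (LD.parameters() if config.use_ld else []),
                 config.lr_d, config.betas)
    opt_s = Adam(S.parameters(), config.lr_s, config.betas)

    x_all, y_all, m_all = _stack(pairs)
    n = len(pairs)
    if config.use_edge:
        xe_all = np.stack([compute_soft_edges(x_all[i, 0]) for i in range(n)])[:, None]
        ye_all = np.stack([compute_soft_edges(y_all[i, 0]) for i in range(n)])[:, None]
    w = config.weights
    ps = config.patch_size
    rows: list[dict] = []
    epoch1_state: dict = {}

    def np_patches(arr, windows):
        return np.stack([arr[i, :, r0:r0 + ps, c0:c0 + ps]
                         for i, (r0, c0) in enumerate(windows)])

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb, mb = x_all[idx].copy(), y_all[idx].copy(), m_all[idx].copy()
            if config.use_edge:
                xeb, yeb = xe_all[idx].copy(), ye_all[idx].copy()
            else:
                xeb = yeb = np.zeros_like(xb)
            if config.augment:
                # Sobel magnitude is equivariant under the vertical flip, so
                # precomputed edge maps flip with their slices
                for i in range(len(idx)):
                    if rng.random() < 0.5:
                        xb[i] = xb[i, :, ::-1]
                        yb[i] = yb[i, :, ::-1]
                        mb[i] = mb[i, ::-1]
                        xeb[i] = xeb[i, :, ::-1]
                        yeb[i] = yeb[i, :, ::-1]
            windows = [crop_window(mb[i], ps) for i in range(len(idx))]
            xt, yt, mt = Tensor(xb), Tensor(yb), Tensor(mb[:, None])
            xe_bin = (xeb >= 0.4).astype(np.float32)
            ye_bin = (yeb >= 0.4).astype(np.float32)

            # one generator forward serves both the critic update (detached)
            # and the generator update (graph reused after the critic step)
            gx = G(xt)
            gxe = soft_edges_t(gx) if config.use_edge else None
            gxe_bin = ((gxe.data >= 0.4).astype(np.float32) if config.use_edge
                       else np.zeros_like(xb))

            # ---- discriminator step
            opt_d.zero_grad()
            rs, _ = GD(Tensor(np.concatenate([xb, xe_bin, yb, ye_bin], axis=1)))
            fs, _ = GD(Tensor(np.concatenate([xb, xe_bin, gx.data, gxe_bin], axis=1)))
            d_global = hinge_d_loss(rs, fs)
            d_total = d_global
            d_local = None
            if config.use_ld:
                real_p = np.concatenate([np_patches(a, windows)
                                         for a in (xb, xe_bin, yb, ye_bin)], axis=1)
                fake_p = np.concatenate([np_patches(a, windows)
                                         for a in (xb, xe_bin, gx.data, gxe_bin)], axis=1)
                lrs, _ = LD(Tensor(real_p))
                lfs, _ = LD(Tensor(fake_p))
                d_local = hinge_d_loss(lrs, lfs)
                d_total = d_total + d_local
            d_total.backward()
            opt_d.step()

            # ---- segmentor step (target enhanced images only)
            s_val = None
            if config.use_segmentor:
                opt_s.zero_grad()
                s_l = seg_loss(S(yt), mt)
                s_l.backward()
                opt_s.step()
                s_val = float(s_l.data)

            # ---- generator step (critics and segmentor act as fixed parties)
            opt_g.zero_grad()
            xe_t, ye_t = Tensor(xeb), Tensor(yeb)
            with frozen(GD, LD):
                fake_in = cat([xt, Tensor(xe_bin), gx,
                               binarize_st(gxe) if config.use_edge else Tensor(np.zeros_like(xb))],
                              axis=1)
                gfs, feat_fake = GD(fake_in)
                _, feat_real = GD(Tensor(np.concatenate([xb, xe_bin, yb, ye_bin], axis=1)))
                adv = [hinge_g_loss(gfs)]
                ld_feats = None
                if config.use_ld:
                    gp = extract_patches(gx, windows, ps)
                    gep = (extract_patches(gxe, windows, ps) if config.use_edge
                           else Tensor(np_patches(np.zeros_like(xb), windows)))
                    fake_lp = cat([Tensor(np_patches(xb, windows)),
                                   Tensor(np_patches(xe_bin, windows)),
                                   gp,
                                   binarize_st(gep) if config.use_edge else gep],
                                  axis=1)
                    glfs, lfeat_fake = LD(fake_lp)
                    _, lfeat_real = LD(Tensor(real_p))
                    adv.append(hinge_g_loss(glfs))
                    ld_feats = (lfeat_real, lfeat_fake)
            l1_total, report = generator_l1_loss(
                xt, yt, gx, mb, S, GD, LD, w, epoch, ps,
                use_edge=config.use_edge, use_ld=config.use_ld,
                use_segmentor=config.use_segmentor,
                x_edge=xe_t, y_edge=ye_t, gx_edge=gxe,
                gd_feats=(feat_real, feat_fake), ld_feats=ld_feats)
            g_obj = generator_objective(adv, l1_total, w)
            g_obj.backward()
            opt_g.step()

            row = {"epoch": epoch, "step": start // config.batch_size,
                   "d_global": float(d_global.data),
                   "g_adv": float(sum(a.data for a in adv)),
                   "g_total": float(g_obj.data)}
            if d_local is not None:
                row["d_local"] = float(d_local.data)
            if s_val is not None:
                row["s_loss"] = s_val
            row.update(report)
            rows.append(row)

        if epoch == 1:
            epoch1_state = {k: v.copy() for k, v in G.state_dict().items()}
        if config.checkpoint_dir:
            save_checkpoint(Path(config.checkpoint_dir) / f"epoch_{epoch:03d}.npz",
                            bundle, config, normalizer)

    log = pd.DataFrame(rows)
    return TrainResult(bundle=bundle, log=log, config=config,
                       epoch1_g_state=epoch1_state, normalizer=normalizer)


def synthesize(bundle: NetworkBundle, pre_slices, batch_size: int = 8,
               normalizer: NormalizationSpec | None = None,
               denormalize: bool = False) -> list[np.ndarray]:
    """Run the trained generator on normalized pre-contrast slices.

    Inputs must already be in [-1, 1] (the stored normalization); outputs are
    in [-1, 1], or in intensity units when ``denormalize`` is set.
    """
    from .preprocessing import invert_normalizer

    slices = [np.asarray(s, dtype=np.float32) for s in pre_slices]
    for s in slices:
        if s.min() < -1.0001 or s.max() > 1.0001:
            raise ValueError("inputs must be normalized to [-1, 1] with the stored spec")
    if denormalize and normalizer is None:
        raise ValueError("denormalize requires the stored normalization spec")
    G = bundle.G
    G.eval()
    out = []
    for start in range(0, len(slices), batch_size):
        xb = np.stack(slices[start:start + batch_size])[:, None]
        yb = G(Tensor(xb)).data[:, 0]
        out.extend(list(yb))
    G.train()
    if denormalize:
        out = [invert_normalizer(o, normalizer) for o in out]
    return out


# ------------------------------------------------------------- checkpointing
def save_checkpoint(path, bundle: NetworkBundle, config: TrainConfig,
                    normalizer: NormalizationSpec | None = None):
    """Write all four parameter sets (npz) plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name, mod in bundle.modules().items():
        for k, v in mod.state_dict().items():
            arrays[f"{name}::{k}"] = v
    np.savez(path, **arrays)
    sidecar = {"config": asdict(config),
               "normalizer": None if normalizer is None else {"clip_max": normalizer.clip_max}}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path):
    """Rebuild the bundle, config and normalizer from a checkpoint."""
    path = Path(path)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    cdict = sidecar["config"]
    cdict["betas"] = tuple(cdict["betas"])
    cdict["weights"] = LossWeights(**cdict["weights"])
    config = TrainConfig(**cdict)
    bundle = build_bundle(config)
    with np.load(path) as data:
        states: dict[str, dict] = {"G": {}, "GD": {}, "LD": {}, "S": {}}
        for key in data.files:
            name, _, rest = key.partition("::")
            states[name][rest] = data[key]
    for name, mod in bundle.modules().items():
        mod.load_state_dict(states[name])
    norm = sidecar["normalizer"]
    normalizer = None if norm is None else NormalizationSpec(**norm)
    return bundle, config, normalizer


# ------------------------------------------------------------ phantom pairs
def phantom_slice_pairs(params: PhantomParams, n_pairs: int,
                        normalizer: NormalizationSpec | None = None,
                        ) -> tuple[list[SlicePair], NormalizationSpec]:
    """Generate phantom subjects and cut them into normalized slice pairs.

    Subjects are generated until ``n_pairs`` tumor slices are available; the
    normalization is fitted on the generated enhanced slices unless an
    existing spec is supplied (the held-out convention).
    """
    from .phantoms import generate_subject
    from .preprocessing import apply_normalizer

    raw: list[tuple[np.ndarray, np.ndarray, np.ndarray, int, int]] = []
    subject_index = 0
    while len(raw) < n_pairs:
        pre, ce, mask = generate_subject(params, subject_index)
        for idx in range(mask.data.shape[0]):
            if mask.data[idx].any():
                raw.append((pre.data[idx], ce.data[idx], mask.data[idx],
                            subject_index, idx))
        subject_index += 1
        if subject_index > 10 * max(params.n_subjects, 1) + 100:
            raise RuntimeError("could not generate enough tumor slices")
    raw = raw[:n_pairs]
    if normalizer is None:
        normalizer = fit_normalizer([ce for _, ce, _, _, _ in raw])
    pairs = [SlicePair(pre=apply_normalizer(p, normalizer),
                       ce=apply_normalizer(c, normalizer),
                       mask=m.astype(np.uint8), subject_id=f"subject_{si:03d}",
                       slice_index=idx)
             for p, c, m, si, idx in raw]
    return pairs, normalizer


def tumor_patch_l1(G, pairs: list[SlicePair], patch_size: int) -> float:
    """Mean absolute tumor-patch error of the generator on held-out pairs."""
    G.eval()
    errs = []
    for p in pairs:
        gx = G(Tensor(p.pre[None, None])).data[0, 0]
        r0, c0 = crop_window(p.mask, patch_size)
        errs.append(np.abs(gx[r0:r0 + patch_size, c0:c0 + patch_size]
                           - p.ce[r0:r0 + patch_size, c0:c0 + patch_size]).mean())
    G.train()
    return float(np.mean(errs))


def convergence_study(n_seeds: int = 10, n_train: int = 60, n_heldout: int = 16,
                      epochs: int = 10, base_seed: int = 0,
                      config: TrainConfig | None = None) -> pd.DataFrame:
    """Seeded desk-scale learning study on tiny phantoms.

    For each seed, trains the full model and compares held-out tumor-patch L1
    of the final generator against the epoch-1 snapshot and against the
    copy-the-input baseline.  Returns one row per seed.
    """
    rows = []
    for k in range(n_seeds):
        seed = int(base_seed) + k
        cfg = config if config is not None else TrainConfig.tiny(
            epochs=epochs, batch_size=10, seed=seed)
        cfg = replace(cfg, seed=seed, epochs=epochs)
        params = PhantomParams.tiny(seed=seed)
        train_pairs, norm = phantom_slice_pairs(params, n_train)
        held_params = PhantomParams.tiny(seed=seed + 100_000)
        held_pairs, _ = phantom_slice_pairs(held_params, n_heldout, normalizer=norm)

        result = train(cfg, train_pairs, normalizer=norm)
        final_l1 = tumor_patch_l1(result.bundle.G, held_pairs, cfg.patch_size)

        g1 = build_bundle(cfg).G
        g1.load_state_dict(result.epoch1_g_state)
        epoch1_l1 = tumor_patch_l1(g1, held_pairs, cfg.patch_size)

        copy_l1 = float(np.mean([
            np.abs(crop_tumor_patch(p.pre, p.mask, cfg.patch_size)
                   - crop_tumor_patch(p.ce, p.mask, cfg.patch_size)).mean()
            for p in held_pairs]))
        rows.append({"seed": seed, "final_l1": final_l1, "epoch1_l1": epoch1_l1,
                     "copy_l1": copy_l1,
                     "improved": final_l1 < epoch1_l1 and final_l1 < copy_l1})
    return pd.DataFrame(rows)
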