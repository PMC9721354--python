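# Methods

## Model and training procedure

Four parameterized functions are trained per step, in this order: (a) both
discriminators take one hinge-loss update against the current generator's
detached output; (b) the segmentor takes one BCE+Dice update on the target
enhanced image only (never on synthesized images, so its guidance stays
anchored to real enhancement patterns); (c) the generator takes one update
on λ_adv·(hinge terms from both critics) plus the seven-term L1 objective.
Epochs are indexed from 1 for the curriculum weight λ_curr(e) = min(5e, 100).
During the generator step the critics and segmentor participate as fixed
feature extractors: their parameters are detached from the graph, so the
generator objective assigns them exactly zero gradient, and their buffers
(batch-norm running statistics, spectral-norm power-iteration vectors) are
not advanced. Optimization is Adam with learning rate 2e−4 and momentum
parameters (0.5, 0.999) for all four parties — the customary setting for
hinge-loss image-to-image GANs; the independent downstream segmentation
U-Net instead uses Adam's standard 1e−3, since it is a plain supervised
task and 2e−4 is needlessly slow for it.

Assumptions inherited from the data contract: inputs are nonnegative MRI
magnitudes; pre- and post-contrast images of a subject are spatially
aligned (no registration is performed); one tumor ROI per subject; slices
without tumor are excluded from training.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| λ_global / λ_edge | 300 / 20 | — | whole-image intensity and edge similarity weights |
| λ_curr slope / cap | 5 per epoch / 100 | — | tumor-term curriculum; cap reached at epoch 20 |
| λ_adv / λ_fm | 5 / 1 | — | adversarial and feature-matching weights |
| edge threshold | 0.4 | — | binarization of per-image-normalized Sobel maps |
| patch size | 64 (full), 16 (tiny) | px | tumor-centered crop for LD and local terms |
| normalization clip | training-set ceT1 max | intensity | shared scale keeps enhancement across phases |
| tumor exclusion | 3.6 cm² (= 360 px at 1 mm) | area | per-slice rule in the downstream study |

The tiny profile (64×64 images, base width 8, patch 16) scales every spatial
contract by 4 while preserving all structural invariants (score-grid and
penultimate-map sides, attention placement at side image/4).

## Edge maps

Soft maps are (|Sobel_h| + |Sobel_v|) / max, with reflect padding and the
maximum taken per image so the fixed 0.4 threshold is meaningful across
slices; a zero image maps to a zero map. The ≥ convention holds at the
threshold. In generator loss terms the *soft* maps are used (hard
thresholding has zero gradient almost everywhere) with the normalizing
maximum treated as a constant; critics receive *binarized* maps with
straight-through gradients. The local critic and the tumor-edge L1 term use
tumor-centered crops of the full-image edge maps, not Sobel re-run on the
crop, mirroring the crop-after-compute evaluation protocol.

## Phantom generator

The phantom emulates exactly the structure the model assumes: an air
background (≈0 intensity), a half-elliptical breast over a chest-wall band
with band-limited texture (Gaussian-smoothed white noise, correlation
length `texture_scale`), one ellipsoidal tumor with internal multiplicative
texture, and `ceT1 = field · preT1 + noise` with field = 2.2 inside the
tumor, 1.15 in breast tissue, 1 in air. The tumor border is an outward
smoothstep ramp over ~2 px: the binary mask region carries the full tumor
gain, so the empirical mask-mean contrast equals the nominal ratio exactly
at zero noise, while edge maps still see a finite-width border. Internal
tumor texture lives in preT1 and is inherited by ceT1 through the
multiplicative field. Default gains (2.2 / 1.15) reflect the strong
early-phase tumor enhancement and mild parenchymal enhancement typical of
breast DCE-MRI.

What the phantom does **not** model: pharmacokinetic (Tofts-type) washin/
washout dynamics, bias fields, coil profiles, motion or misregistration
between phases, multi-focal disease, and non-mass enhancement. Passing the
desk-scale studies therefore demonstrates that the implementation learns
and evaluates correctly under its stated assumptions — not that the
architecture reaches any particular fidelity on patient data.

## Evaluation conventions

NRMSE = 100·RMSE / normalizer, with the normalizer configurable (target
dynamic range by default; mean or RMS alternatives) because the quantity is
only comparable within one convention. PSNR uses the target's own range by
default (fixed R = 2 available for [−1,1] data). SSIM is scikit-image's
Gaussian-window form (11×11, σ = 1.5, population covariance); below 11 px
the largest odd uniform window is used. Degenerate inputs (constant target)
yield NaN rather than silent zeros; identical images report PSNR = +inf.
Methods are compared per slice by a two-sided sign-flip permutation test,
p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm).

ASSD uses boundary = mask minus its 4-connected erosion and exact Euclidean
distance transforms; an empty prediction against a nonempty label is DSC 0
with ASSD undefined (NaN). The 3.6 cm² exclusion is applied per slice at
1 mm isotropic pixels with a ≥ inclusion convention.

## Numerical choices

The networks run on a small reverse-mode autodiff engine over float32 numpy
arrays (convolutions via patch-matrix GEMMs, optionally numba-accelerated;
fused batch normalization; spectral normalization by one power iteration
per training forward with σ treated as constant in backward). Dice uses
ε = 1e−6; BCE clips probabilities to [1e−7, 1−1e−7]. Centroids round
half-up; crop windows clamp to the image instead of padding. Batch-norm
eval mode uses running statistics; all forwards are deterministic given
parameters, and one seed drives initialization, shuffling, augmentation and
phantom sampling, so identical configurations reproduce bit-identical
training.

## Desk-scale study sizes

The seeded studies run at the tiny profile with sizes chosen for a
single-CPU desk run: the generator convergence study uses 10 seeds × (24
training pairs, 14 epochs, batch 10, 12 held-out pairs) and requires the
final generator's held-out tumor-patch L1 to beat both the epoch-1 snapshot
and the copy-the-input baseline; the downstream segmentation study uses 10
seeds × (24 pairs, 64 epochs, batch 4, 10 held-out) against an untrained
network's Dice. Both complete in a few minutes; the tumor-area exclusion is
exercised with constructed masks (at 64×64 the phantom tumors themselves
are below 3.6 cm², as real small tumors would be).

## Known limitations

2-D slices only (no 3-D or stacked-slice variants); a single tumor per
subject; the engine is CPU-bound and intended for desk-scale verification
and method study, not full-resolution clinical training; absolute metric
values on phantoms are not comparable to values on patient cohorts.
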