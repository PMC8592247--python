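# Methods

## The problem and the approach

Convolutional classifiers for thorax disease on frontal chest
radiographs tend to latch onto disease-specific texture and treat the
rest of the image — rib cage, shoulder girdle, spine — as background.
`cxrprior` implements the opposite curriculum: the network is first
made to learn *anatomical* structure by training it to predict gender
and age from images whose disease detail has been deliberately
suppressed, and only then retrained for multi-label disease detection
on unmodified images.  The package provides every stage of that
pipeline plus a synthetic phantom generator so the whole method can be
exercised and tested end to end on one CPU, without any clinical data.

## Phantom generator

A phantom is a square 8-bit image with five structures on a dark
background, all placed in fractions of the image side so the anatomy is
scale-free: two lung-field ellipses (centers at (0.56, 0.30) and
(0.56, 0.70), semi-axes 0.26·aspect vertically and 0.15 horizontally),
a central spine column (width 0.10), and two shoulder bands (top at
0.06, base thickness 0.09).  Labels influence geometry only:

* **Gender** scales the shoulder-band thickness by `1 ± effect/2`
  (Male thicker).  The default effect of 0.3, with 5% per-subject
  multiplicative jitter, makes a logistic fit on band width alone
  exceed 90% accuracy — the generator's recoverability contract.
* **Age** (four bins: 1–10, 11–20, 21–30, 31–120 years; closed below,
  open above) adds a monotone delta to the lung-ellipse vertical
  aspect: (−0.24, −0.08, +0.08, +0.24) by default.  The deltas are
  sized so that adjacent bins differ by more than a pixel at the 32-px
  desk scale even after NMF compression; smaller deltas leave the age
  task unlearnable at that scale, which would defeat the purpose of an
  anatomy curriculum.
* **Disease** labels (the 14 ChestX-ray14 classes) each add one
  Gaussian blob (default peak 0.4 of the gray range, radius 8 px at
  the 128-px default) at a class-specific position inside a lung
  ellipse.  Blob centers stay inside the ellipses and below the
  shoulder bands, so anatomical and pathological signal never overlap
  spatially.  Per-class prevalence is an independent Bernoulli draw
  (default 0.08); a subject with no label is "No Finding".

All randomness flows from a single `numpy` generator seeded by the
config, so identical configs give byte-identical image sets.  What the
phantoms do **not** emulate: radiographic texture, ribs, projection
physics, label noise, inter-label correlation, or patient-level
structure.  Tests passing on phantoms therefore demonstrate that the
pipeline's machinery behaves as specified — not that the method's
clinical-scale performance transfers.

## Preprocessing (Ver_ORG / Ver_NMF)

The training pool is rotation-augmented (angles uniform in ±30°,
corners filled black, originals retained) until each class reaches the
majority count; for multi-label views a rotated copy counts toward all
its labels, so balancing is exact for single-label views and
best-effort otherwise.  Validation and test images are never
augmented.

Two versions of the pool are then built, sharing ids, labels and
roles:

* **Ver_ORG** — the augmented originals.
* **Ver_NMF** — each image is treated as a non-negative matrix and
  factorized as Λ ≈ ΨH at rank κ by multiplicative updates; the
  clipped 8-bit reconstruction ΨH is the compressed image, which is
  then passed through CLAHE.  Rank κ must satisfy κ < nm/(n+m).  The
  default is κ = 6, chosen from the suppression mechanism itself: the
  phantom anatomy has an effective rank of about 5 regardless of image
  size (bands and the spine are rank 1–2 patterns, the ellipses a few
  more), so a rank budget just above it reconstructs anatomy while
  leaving little capacity for blobs.  On these geometric phantoms the
  suppression is real but partial and class-dependent: measured over
  the 14 blob placements on 64-px phantoms, mean local blob contrast
  retained is ~71% at κ = 4, ~90% at κ = 5–6, and essentially 100% at
  κ ≥ 12 (favorably placed blobs drop to ~45% at low rank).  Pushing κ
  below 4 would start erasing the rib-cage ellipses whose aspect ratio
  carries the age signal, so the default sits at the anatomy rank
  rather than below it.  Relatedly, the disease
  blobs are rendered as *tilted anisotropic* Gaussians (2.5:1,
  class-specific orientation): an axis-aligned isotropic Gaussian is
  an exactly separable rank-1 pattern that NMF preserves at any rank,
  which would silently disable the suppression stage.  Both the
  Frobenius objective ‖Λ−ΨH‖ and a
  Poisson/KL ("log-form") objective are implemented; each is monotone
  non-increasing along its update sequence, and the recorded objective
  trace makes that checkable.  Initialization is uniform random scaled
  by √(mean(Λ)/κ), seeded.
* **CLAHE** is scikit-image's implementation behind the package's
  config surface: a tile grid NT (default 8×8; images are padded by
  edge replication to a tile multiple and cropped back) and a relative
  clip limit CL (default 2.0, i.e. twice the uniform histogram
  height; mapped to scikit-image's normalized clip limit as CL/256).
  A constant image passes through unchanged.  Re-applying CLAHE to an
  already-equalized image moves its 16-bin gray histogram by less than
  0.5 total variation on the bundled fixtures — a regression
  tolerance, not a theorem.

The train/val/test split is 80/10/10, stratified: single-label views
stratify on the class; multi-label records group by the rarest label
they carry (a cheap proxy for iterative stratification).  Within a
stratum, seats are allocated by largest remainder; remainder ties go
to the globally most under-allocated role, train first — this makes
per-class 4/1/0 vs 4/0/1 assignments alternate instead of piling onto
one role.  Strata with fewer than three records go wholly to train
with a warning.  The assignment is made once and shared by both
versions.

## Dual-stream network

Two parallel streams see the same grayscale input: stream S1 uses 3×3
kernels throughout, S2 uses 5×5.  Each stream is three blocks of
[conv → ReLU → conv → batch-norm → ReLU → dropout(0.25) → 2×2
max-pool], with "same" padding so only pooling changes the spatial
size (hence the input side must be divisible by 8).  Default filter
widths are (16, 32, 64) per block; the desk-scale studies use
narrower variants.  The flattened stream outputs F_S1 and F_S2 are
concatenated into F_total and a single dense layer maps F_total to one
length-8 embedding vector ν_k per class.  Each ν_k is squashed
(v = (‖s‖²/(1+‖s‖²))·s/‖s‖) so its norm lies in [0, 1), and the class
score is ‖ν_k‖.  Single-label tasks predict the argmax score;
multi-label tasks threshold each score at 0.5 — meaningful because
the squash bounds norms.  The dense head's initial weights are scaled
down (×0.5) so initial norms sit in the squash map's responsive range
rather than its saturated tail, where gradients vanish.

Each input image is standardized to zero mean and unit variance
inside the model (configurable).  This matters for the sequential
protocol: the CLAHE-equalized Ver_NMF images and the raw Ver_ORG
images occupy very different intensity ranges, and without
standardization a backbone trained on one version transfers poorly to
the other — the phase-3 fine-tuning then fights the domain shift
instead of reusing anatomy features.

The layers are implemented directly in NumPy (im2col convolution,
explicit backward passes, Adam), which keeps the package dependency-
light and makes intermediate activations and their gradients — which
Grad-CAM needs — first-class objects.  A finite-difference harness in
the test suite checks every layer's gradients in float64.

## Margin loss

Per class k with binary target T_k,

    Γ_k = T_k·max(0, m⁺ − ‖ν_k‖²) + λ(1−T_k)·max(0, ‖ν_k‖² − m⁻),

with m⁺ = 0.9, m⁻ = 0.1, λ = 0.5; the total is the sum over classes,
averaged over the batch.  Note the square sits on the norm *inside*
the hinge; the capsule-network original squares the hinge instead and
is available behind `squared_hinge_variant` for comparison.  Optional
per-class weights (inverse training-split frequency, normalized to
mean 1) are off by default.

## Training protocol

Stage II runs up to three sequential phases — gender on Ver_NMF, age
on Ver_NMF, disease on Ver_ORG — with Adam.  Full-scale defaults
follow the protocol: learning rate 0.001 and 10 epochs for the
anatomy phases, 0.0001 and 100 epochs for disease.  Between phases the
stream backbones (weights and batch-norm running statistics) carry
over bit-exactly while the head is reinitialized for the new class
count.  The best checkpoint of a phase is selected by validation
accuracy (anatomy) or validation macro-AUC (disease).  Nine named
variants (GD_NMF, AD_NMF, DD_ORG, and the partial/full chains like
`GD_NMF => AD_NMF => DD_ORG`) encode every ablation through one code
path.  Batch size defaults to 32.

## Grad-CAM and zone profiling

For class c the score y^c = ‖ν_c‖ is differentiated with respect to
the feature maps A^k of the last conv layer; the spatial mean of the
gradient is the weight a_k^c, and the map is ReLU(Σ_k a_k^c A^k),
bilinearly upsampled to the input.  Because the network has two
streams, a map is computed at each stream's last conv layer and the
two upsampled maps are averaged (single-stream maps are available).

Attention is quantified over a 3×3 grid of zones Z11…Z33 (row band,
column band, origin top-left; remainder pixels of a side not divisible
by 3 join the last band).  For each *correctly classified* image of a
class, the min-max-normalized map's mean intensity per zone is
normalized to sum to 1; the class profile is the mean of those
per-image vectors.  Averaging intensities (rather than counting
thresholded "zone hit" events) is a documented interpretation choice;
with no qualifying image the profile is returned empty rather than
raising.

## Desk-scale studies

Two studies in `cxrprior.experiments` back the package's claims at a
scale one CPU can handle; `scripts/acceptance.py` re-runs both from
scratch.

**Sequential transfer.**  500 phantoms at 32 px (gender effect 0.4,
blob intensity 0.5, radius 2 px, prevalence 0.10), NMF κ=8, CLAHE 4×4;
network widths (6, 12, 24).  The epoch budget scales the protocol
down: 5 epochs per anatomy phase at lr 0.001, 15 disease epochs at the
protocol's ten-fold smaller lr 0.0001.  That small disease rate is the
crux of the design at this scale: it preserves whatever features
phase 1–2 built, so a chain with useful anatomy features can adapt
while a from-scratch baseline is slow to leave its random
initialization.  Over five seeded replicates the chain's mean test
macro-AUC is expected to be at least the baseline's minus 0.02 — the
tolerance acknowledges that with ~50 test images and ~5 positives per
class, per-seed macro-AUC carries sampling noise of a few points.

**Grad-CAM localization.**  80 planted-patch images (positive class =
bright square in zone Z11), 10 training epochs; the positive class's
zone profile should put its maximum on Z11 in at least 4 of 5 seeds.
When a seed misses, the maximum lands on a zone adjacent to Z11: at
32-px inputs the final conv layer's 8×8 maps are upsampled 4× and the
stacked 3×3/5×5 receptive fields span most of the image, so zone-level
attribution carries an intrinsic blur of roughly one zone.  Larger
inputs sharpen it; the study size keeps the whole suite CPU-friendly.

## Known limitations

* Phantom realism is intentionally minimal (see above); absolute AUC
  values on phantoms say nothing about clinical data.
* The NumPy network is single-threaded BLAS-bound; it is sized for
  32–128 px inputs, not full-resolution radiographs.
* Multi-label rotation balancing can overshoot majority counts when
  labels co-occur.
* Macro-AUC on small test splits is noisy; the transfer study's
  per-seed spread (±0.05 or more) is dominated by this, which is why
  conclusions rest on seed-averaged means.
* The log-form NMF objective is reported as the (equivalent, sign-
  flipped) KL divergence so that "monotone non-increasing" means the
  same thing for both objectives.
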