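# Methods

## Problem and scope

The package segments lung parenchyma (both lungs, trachea excluded) on
volumetric thin-section chest CT, in Hounsfield units (HU), for cohorts with
fibrotic interstitial disease. Everything runs on synthetic phantoms with
exact ground truth; no patient data is bundled or required.

## Geometry and preprocessing

Input studies may arrive at mixed in-plane matrices (e.g. 720×720 and
672×672 from different scanners). All studies are resampled to isotropic
1×1×1 mm with endpoint-aligned linear interpolation (nearest-neighbour for
masks, which therefore remain strictly binary), then center-cropped or
padded in-plane to a fixed matrix (512×512 by default), padding with air
(−1000 HU). Resampling and crop/pad are done in that order so the physical
scale of anatomy is preserved; the alternative — anisotropic scaling straight
to 512×512 — would distort lung shape across scanners. Linear interpolation
is convex, so resampled intensities never leave the input min/max.

Training inputs are standardized pixel-wise: a 2D mean image and a 2D
population-std image are computed over *all training slices of a fold*, and
each slice is transformed to (x − mean) / max(std, ε) with ε = 1e−7. The ε
guards pixels with zero variance (padded corners); standardization is exactly
invertible wherever std > ε. Statistics are computed per fold from the
training folds only, never from validation or test studies.

## Architectures

**Modified U-Net.** Four resolution levels with 32/64/128/256 feature maps
(a 512×512 input reaches a 64×64 bottom plane after three 2×2 max pools).
Every stage applies two biased, zero-padded k×k convolutions (k = 3 or 5),
each followed by ReLU and a 10% dropout. The decoder uses parameter-free
nearest-neighbour 2× upsampling followed by concatenation with the matching
encoder stage (decoder first-conv input channels 384/192/96 for the default
widths) and two more conv/ReLU/dropout blocks; the head is a biased 1×1
convolution to two classes with per-pixel soft-max, channel 0 = lung. The
parameter total therefore obeys the closed form Σ k²·c_in·c_out + c_out over
all convolutions: 1,946,338 trainable weights at k = 3 and 5,403,874 at
k = 5, with no non-trainable parameters. A transposed-convolution decoder
was rejected because it cannot reproduce these ledger totals; the ReLU after
each convolution is the canonical choice (it carries no weights, and without
a nonlinearity between convolutions the network is almost linear and
demonstrably cannot fit the task).

**E-Net.** The compact real-time bottleneck design: an initial block (3×3
stride-2 conv to 15 filters concatenated with a max pool of the 1-channel
input, giving 16 channels), five encoder bottlenecks at 64 channels, a
downsampling bottleneck to 128, then two groups of eight bottlenecks
alternating regular, dilated (rates 2/4/8/16) and asymmetric (5×1 followed by
1×5) convolutions; the decoder has upsampling bottlenecks (3×3 transposed
conv in the main path; bias-free 1×1 conv + batch norm + nearest 2× on the
residual path) back to 64 and 16 channels and a final 2×2 transposed conv to
two classes. Each bottleneck is 1×1 projection → main conv → 1×1 expansion,
all batch-normalized, with per-channel PReLU in the encoder and plain ReLU in
the decoder, spatial dropout (0.01 in the first stage, 0.1 later) and a
residual skip (max pool + zero-padded channels when downsampling). Biases are
carried only by the initial conv, the regular/dilated 3×3 convs, the second
asymmetric conv, the decoder 3×3/transposed convs and the final projection —
the convention of the reference Keras implementation of E-Net, and the only
one whose ledger reproduces the reference totals exactly: 362,992 trainable
parameters and 8,352 non-trainable (the batch-norm moving means and
variances — 2×4,176 normalized channels). An asymmetric 5×1+1×5 pair holds
10 weights per channel pair against 25 for a full 5×5.

Weight initialization is fan-in-scaled normal with a configurable seed.
Both builders expose an ordered layer ledger; `count_parameters` sums weight
elements over it, split by trainability, and the test suite re-sums the
ledger through an independent code path.

**Numerical kernel.** No deep-learning framework is used: layers run on a
small reverse-mode autodiff engine over numpy arrays (convolutions — plain,
strided, dilated and transposed — via either an im2col GEMM or a
kernel-tap loop, chosen by buffer size; 2×2 max pooling with argmax
scatter; nearest upsampling; batch normalization with momentum-0.9 moving
statistics; PReLU; inverted dropout; soft-max). Every operator's gradient is
verified against central finite differences in the test suite, as is the
end-to-end U-Net gradient.

## Loss

Training minimizes 1 − T where T is the soft Tversky index of the lung
probability map: T = Σp₀g₀ / (Σp₀g₀ + α Σp₀g₁ + β Σp₁g₀), with a smoothing
constant of 1e−6 in numerator and denominator to guard empty-lung slices
(tests with non-degenerate inputs set it to 0). Defaults α = 0.3, β = 0.7
penalize false negatives harder. On crisp masks with α = β = 0.5 the index
equals DSC exactly; both-empty pairs score 1 by convention (perfect
agreement on absence).

## Region-growing baseline

`grow_region` returns the connected component (6-connectivity by default;
26 available) of voxels inside [−1024, +200] HU containing a seed.
`segment_lungs_rg` automates it: threshold, discard components touching the
in-plane border (external air and everything attenuation-connected to it,
including the soft-tissue body), keep the two largest remaining components,
and subtract a region grown from the most superior remaining in-window
component (the tracheal lumen). Component-size ties break on the smaller
centroid x-index for determinism. The window's upper bound is the reason the
baseline fails on disease: fibrotic tissue above +200 HU is excluded, which
the phantoms reproduce quantitatively.

## Training protocol

Studies are partitioned into 5 random folds (sizes ⌊n/5⌋ with one fold
absorbing the remainder — 6/6/6/6/8 for 32 studies). Each fold model trains
on all axial slices of the other four folds with on-the-fly augmentation:
one sampled geometric transform per slice (rotation ±10°, x/y translation
±10%, shear ±5°, horizontal flip p = 0.5, zoom 0.9–1.1 — mild conventional
ranges, all configurable), applied identically to image (linear, air fill)
and mask (nearest, zero fill) before standardization. Optimization is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−7) with a global gradient-norm clip of 1.0,
batch of 8 slices, reshuffled each epoch with the pipeline seed, last
partial batch kept. Default learning rates are 1e−4 (E-Net) and 1e−5
(U-Net). "No improvement" means no strict decrease of the epoch-mean
training loss below the best value seen; after 10 such consecutive epochs
training stops (or at 100 epochs). Inference standardizes each slice with
the fold's statistics, runs the network in inference mode and takes the
per-pixel arg-max (equivalently p₀ ≥ 0.5 for two classes). Held-out test
studies are predicted by all five fold models and metrics are averaged
across models, not ensembled at the mask level.

## Evaluation

Per study: sensitivity TP/(TP+FN), PPV TP/(TP+FP), DSC 2TP/(2TP+FP+FN),
VOE 1 − Jaccard, signed VD (|P|−|G|)/|G| (over-segmentation positive), all
in percent, and ASSD in physical mm — surfaces are mask voxels with a
face-adjacent background voxel; distances are Euclidean with voxel spacing,
averaged symmetrically over both surfaces. Empty-truth cases flag
sensitivity/VD as NaN rather than raising. Summaries report mean, sample
std (n−1) and a normal-approximation 95% CI (1.96·std/√n). Method
comparison uses two-group one-way ANOVA on per-study DSC, reported as F,
the 5% critical value, and p (identical to the squared pooled two-sample
t statistic); identical groups define F = 0, p = 1.

## Phantom generator

Each phantom is a torso-like scene: air background (−1000 HU), ellipsoidal
soft-tissue body (+40), two ellipsoidal lungs (−800) whose exact voxel sets
are the ground truth, and an air-filled tracheal tube excluded from the
truth. Two deliberate design choices make the scene *exactly* segmentable
by the HU-window baseline, which real anatomy only approximates: (i) each
lung and the trachea are wrapped in a thin dense rim (+300 HU — the pleural
line / tracheal cartilage), so seeded growing cannot leak out of a lung;
(ii) the tube is sealed and the soft-tissue body, being attenuation-connected
to the exterior air, is removed by the baseline's border rule. Disease is
emulated by mild patches (ground-glass-like, −300…+100 HU, inside the
window) and a severe peripheral posterior-basal wedge (+250 HU, above the
window) whose depth is calibrated so it holds a requested fraction of the
lung volume — the IPF-like distribution. Gaussian HU noise (configurable,
typically 20 HU) is added last and clipped to [−1024, 3071]. Cohorts draw
in-plane sizes from {720, 672} at the 11:31 ratio of the emulated
two-scanner population, with a few percent of geometric jitter per study and
the scanner tag recorded for stratified splitting.

What the phantoms do **not** emulate: airway trees beyond a single sealed
tube, vasculature, honeycombing texture, pleural effusion, partial-volume
blur at tissue interfaces, or anatomies whose chest wall is itself partly
inside the HU window. Passing tests therefore demonstrate correctness of
the pipeline and the qualitative threshold-versus-learning contrast, not
clinical-grade accuracy on patient HRCT.

## Desk-scale experiment sizes

The learning checks run at reduced scale so the whole suite fits a desk
machine: 8 phantom studies of 64×64×30 voxels (6 train / 2 held out), U-Net
with base_filters 8 and E-Net at width 0.5, learning rates 5e−4 and 1e−3
(the full-scale defaults are far too slow on these small, easy problems),
18 and 16 epoch caps with patience 10, batch 8, Tversky(0.3, 0.7), fixed
seeds throughout. Under these conditions both architectures exceed 90% DSC
on held-out phantoms and the region-growing baseline scores below the
network on severe-fibrosis phantoms. The phantom slice-count default is 60
(configurable to the 600 of full clinical stacks).

## Known limitations

* The numpy kernel is CPU-only and desk-scale; full 512×512 five-fold
  training at clinical volume sizes is out of its intended range.
* DICOM reading covers plain axial series with rescale slope/intercept; no
  multi-frame, gantry-tilt or compressed-transfer-syntax handling.
* The automatic trachea step assumes the lumen is the most superior
  non-lung in-window component; unusual airway anatomy may require an
  explicit seed (supported by `remove_trachea`).
* ANOVA assumes independent per-study DSC values; fold models share
  training data, so the comparison is the usual approximation, not an
  exact design.
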