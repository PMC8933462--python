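# Methods

This note documents the models, algorithms and design choices in
`octaquant`: what the synthetic eye emulates, how the flow-quantification
pipeline is defined, and how the statistical stage is calibrated.

## The quantification pipeline

### Binarization of retinal slabs

Each SCP/DCP image is binarized along two independent chains whose
pixelwise AND is the final flow map:

* **Chain A — vesselness + Huang.** A single-scale Frangi-type vesselness
  is computed from the Hessian eigenvalues at scale σ = 2 px (capillary
  caliber at the working rasters). With |λ₁| ≤ |λ₂|, blobness
  R_b = λ₁/λ₂ and structure norm S = √(λ₁² + λ₂²), the response is
  `exp(−R_b²/2β²)·(1 − exp(−S²/2c²))` where λ₂ < 0 (bright ridges), zero
  elsewhere, rescaled to [0, 1]. β = 0.5 (the standard 2-D value). The
  structure-norm scale defaults to `c = max(S)/16`: capillary ridges are an
  order of magnitude weaker than large-vessel ridges, and a smaller `c`
  saturates the structureness term for them instead of crushing them; being
  proportional to the image's own Hessian norm it also makes the rescaled
  response exactly invariant to positive intensity scaling. The enhanced
  image is quantised to 8 bits and thresholded with Huang's
  minimum-fuzziness criterion (membership `u(g) = 1/(1+|g−μ_class|/C)`,
  Shannon fuzziness, exhaustive search, ties to the lower level).
* **Chain B — local median.** A pixel is flow iff it strictly exceeds the
  median of its circular 15-px window (edge replication). The strict
  inequality makes a perfectly flat image all-background — zero contrast
  means no detectable flow.

A constant image yields an empty map with a warning rather than an
exception, so degenerate inputs flow through cohort runs gracefully.

### Large-vessel mask

Superficial large vessels confound DCP/CC quantification through
projection and shadowing. The mask is built from the SCP image by Gaussian
smoothing (σ = 2 px), Kapur maximum-entropy thresholding of the smoothed
grayscale, morphological opening with a radius-2 disk (removes structures
thinner than ~4 px, i.e. anything of capillary caliber), and a 2-px
dilation to absorb the halo. Maximum entropy is applied to the smoothed
grayscale rather than to an already-binary map because entropy
partitioning of a two-level histogram is degenerate. Masked pixels are
removed from both the numerator and the denominator of every downstream
metric (the analyzed-area convention); excluding them from the numerator
only is available by composing the primitives directly.

### Metrics

`VD = 100·|flow ∧ ¬mask|/|¬mask|`, `VLD` the same on the skeleton, and
`CCFD = 100 − VD` on the CC map — an exact complement on every input.
Skeletonization is Zhang–Suen thinning iterated to a fixed point, followed
by a cleanup that deletes one topologically simple corner of any residual
2×2 block (Zhang–Suen is known to leave 2-px staircase remnants). The
cleanup never sacrifices connectivity: in rare dense configurations where
no corner of a block can be removed without splitting a component, the
block is left in place. Skeletons are therefore idempotent, subsets of the
foreground, and preserve the 8-connected component count exactly.

### Geometry

CC images are processed at twice the retinal raster so that the published
15-px Phansalkar radius corresponds to 43.94 µm at the reference 2048-px
export (6000 µm / 2048 px × 15). Reference single-image geometry is
1024 px (retina) / 2048 px (CC); the cohort experiment defaults to
256/512 px, which preserves every qualitative effect while keeping a
20-subject × 2-device × 3-condition × 3-repeat cohort (1080 quantified
images) around one minute on one CPU. The Phansalkar radius is defined in
pixels, as the method states, so its micron equivalent scales with the
raster.

## The synthetic eye

A phantom is one subject: boolean ground-truth maps plus continuous
amplitude fields.

* **Capillary mesh.** The edge network of a Voronoi tessellation of random
  seed points, rendered as constant-caliber tubes (~3 px). Capillary
  density in the retina varies by intercapillary spacing, not caliber, so a
  requested foreground fraction (defaults: SCP 0.34, DCP 0.38, matching
  healthy-macula vessel densities) is met by adjusting the cell count, with
  a final pixel-level annex/prune at the tube boundary that lands the
  rendered fraction within one pixel of the request. `truth_fractions` are
  exact pixel counts of the final maps.
* **Large vessels.** Four to six random-walk arcades entering from the
  field border, 85–120 µm caliber (≥ 4 px at any raster), with occasional
  branches, stopping short of the fovea; total vessel coverage is capped at
  10 % of the field, as arcade coverage is anatomically bounded. The foveal
  avascular zone (FAZ, 270 µm nominal radius, jittered ellipse) contains no
  flow in either retinal layer.
* **Perfusion heterogeneity.** Capillary signal amplitude varies smoothly
  between 0.15 and 0.85 of a large vessel's (patches of ~8 px): capillary
  decorrelation signal is flow-dependent and the dim tail is what fades
  first under attenuation.
* **Choriocapillaris.** A thresholded Gaussian random field (correlation
  length ~1–3 px) gives the bright/dark "ground glass" alternation; the
  flow fraction defaults to 0.75 (deficits ~25 % at full signal). Rendered
  CC intensity is shadowed under the upscaled large vessels.

### Acquisition and attenuation

Rendered intensity is
`clip(T_eff · template · speckle + n_f · ε, 0, 1)` quantised to 8 bits,
with `T_eff = 10^(−OD·sensitivity)`. The NDF model is single-pass
(`T = 10^(−OD)`, i.e. 50 %/75 % illumination reduction at OD 0.3/0.6, as
the filters are specified), and the device sensitivity multiplier (SD 1.5,
swept-source 1.0) reproduces the qualitative device asymmetry — the
spectral-domain model, with fewer A-scans and a shorter wavelength, loses
signal faster, reaching SS ≈ 3–4 at OD 0.6 while the swept-source model
stays near 5–6. Numeric agreement with any human cohort is not attempted.

Speckle is multiplicative, bounded (0.55 + 0.45·Beta(2, 2) via a Gaussian
copula) and spatially correlated at the PSF scale (~1.5 px); the additive
noise floor (default σ = 0.015) is correlated at ~1 px. Two modelling
points matter here. Bounded speckle keeps noise-free renders strictly
ordered — every true-flow pixel brighter than every background pixel — which
an unbounded heavy-tailed speckle would violate; and spatial correlation
makes a fading capillary disappear as a contiguous segment rather than as
salt-and-pepper holes, whose perforated remnants would otherwise inflate
the skeleton (and hence VLD) under attenuation. Pixels whose value falls
below 2.5× the noise floor are exported as black, emulating the device-side
suppression of low or noisy pixels before display; this is the mechanism
through which attenuation converts dim flow into apparent non-perfusion.

Projection of SCP large vessels into the DCP is an on/off renderer switch
(`projection_removal`, default on, mirroring the devices' embedded
projection removal); the CC shadow term is always present, as shadows are
not removed by projection removal. Repeat scans share the template and
differ only in the speckle and noise draws; every render is a pure
function of (phantom, acquisition setting, repeat index).

### Signal strength

Devices do not publish their SS formula; only the endpoints of the 0–10
scale are well-defined. The score used here is a clamped log mapping of
contrast-to-noise: `CNR = (P99 − P10)/max(n_f, 10⁻³)`, with CNR = 3 (a
structureless noise field) mapping to 0 and CNR = 100 to 10. It is
monotone in signal-to-noise, scores 10 for a noise-free unattenuated
render and 0 for pure noise, and — being built from percentile
differences — is exactly invariant to constant intensity offsets. Only
these properties are asserted; the numeric trajectory between the
endpoints is a stand-in.

## The experiment and statistics

`run_cohort` renders subjects × {SD, SS} × OD {0, 0.3, 0.6} × 3 repeats,
quantifies every slab (the large-vessel mask comes from the same repeat's
SCP render), and averages the three repeats per condition — repeat
averaging damps scan-to-scan flow variation. All randomness derives from
one seed through named SeedSequence streams; a run is bit-identical across
invocations.

Routing: a metric takes the nonparametric path iff Shapiro–Wilk flags any
condition at p ≤ 0.05 (constant samples are flagged non-normal with a
note). The discrete, ceiling-clamped signal strength routes nonparametric
in practice; the flow metrics route parametric. Both p-values of the
normality stage are reported (Shapiro–Wilk decides; the
Lilliefors-corrected Kolmogorov–Smirnov p is informational).

* **Friedman.** Mid-ranks within subjects;
  `Q = n²(k−1)·Σ_j(R̄_j − r̄)² / Σ_ij(r_ij − r̄)²`, which reduces to the
  classic `12n/(k(k+1))·Σ(R̄_j −(k+1)/2)²` without ties; χ² p on k−1 df.
* **Wilcoxon signed-rank.** Zero differences dropped (classic convention —
  software defaults differ), mid-ranks for tied magnitudes,
  `W = min(W⁺, W⁻)`; exact two-sided p for n ≤ 25 from the full
  sign-assignment distribution (dynamic programming over doubled ranks, so
  mid-ranks stay integral), normal approximation with tie and continuity
  corrections above.
* **RM-ANOVA.** Textbook partition into subject/condition/error sums of
  squares, F on (k−1, (n−1)(k−1)) df, Bonferroni-corrected paired t
  post-hocs (m = 3). At k = 2 the omnibus F equals the squared paired t.
* **Correlations.** Pearson r of SS against each metric, pooled over the
  subject × condition means (one point per subject and condition), with an
  OLS line; two-sided t-based p. All tests are two-sided at α = 0.05.

### Calibration notes

Under a null cohort (subject effects plus repeat noise, no condition
effect) both omnibus tests reject at 5.0–6.2 % over 1000 replicates. The
exact Wilcoxon p agrees with full 2ⁿ enumeration to machine precision. For
the Friedman test at n = 5, k = 3, the χ² approximation agrees with the
exact (3!)⁵ permutation p to better than 0.01 throughout the significance
region (exact p ≤ 0.05); in the middle of the null distribution no
continuous approximation can do so uniformly, because the permutation null
is discrete with probability atoms as large as ~0.17 there.

## What the phantom does and does not show

The generator reproduces the qualitative phenomena the pipeline is meant
to probe: monotone attenuation of rendered intensity with OD, capillary
fading into the noise floor, rising CC flow deficits, falling retinal
vessel/length densities, device asymmetry, and a strongly negative
SS–CCFD correlation. It does not model motion artifacts, defocus,
regionally inhomogeneous opacity (an NDF attenuates uniformly across the
field), B-scan/volumetric physics, or device display renormalisation — the
last omission means the linear attenuation model saturates CC deficits
(> 90 %) at the lowest spectral-domain signal level, where real exports
would be display-stretched. Passing tests therefore demonstrate the
internal consistency and direction-of-effect behaviour of the
quantification chain, not numeric agreement with human-cohort tables.

## Numerical and degenerate-input conventions

Global thresholds tie-break toward the lower level; all local operators
use circular windows with edge replication; histograms are 256-bin
(8-bit). Constant images: empty binarization (warning), empty vessel mask,
non-normal flag with note, Friedman/ANOVA p = 1. A mask covering the whole
image raises (undefined denominator). The RM-ANOVA sums of squares are
guarded against catastrophic cancellation on degenerate inputs
(`SS < 10⁻¹²·SS_total` is treated as zero), and a zero error variance with
a nonzero condition effect reports an unbounded F with a note. Phansalkar
local moments are computed by FFT convolution of an edge-padded image;
agreement with the direct per-pixel definition is exact at binary-decision
level on every tested input.

## Problem sizes used in tests

The default test run uses 64–256 px rasters, a 20-subject cohort at the
256/512-px cohort raster for the direction-of-effect checks, 1000
replicates for type-I calibration, and full enumeration/permutation
oracles at n ≤ 10 (Wilcoxon) and n = 5, k = 3 (Friedman). These sizes were
chosen so the full suite exercises every claim in minutes on a single CPU.
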