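# Methods

## Scope and data model

`ccrings` quantifies choriocapillaris (CC) flow deficits in concentric rings
around a type-1 MNV lesion on co-registered en face OCTA image pairs
(angiogram + structural slab), with the MNV, dark-halo, and
superficial-vessel masks supplied as inputs (in clinical use they are drawn
by graders; the package does not segment). All rasters carry a physical pixel
pitch; the reference geometry is a 3 × 3 mm scan at 500 × 500 px (6.0 µm/px).
Analyses start from 2-D en face images — volume processing and slab
segmentation are out of scope.

## Shadow compensation

Large retinal vessels and lesion material attenuate both the structural slab
and the angiogram beneath them. Compensation computes
`angiogram ⊙ (I_max − structural)` in float64 and min–max rescales the
product to the angiogram's bit depth. This is the most literal reading of the
invert-and-multiply scheme; no smoothing, clipping, or gamma is applied, and
whether to rescale or clip after multiplication was an open choice — min–max
rescaling is ours, documented here. A flat product (e.g. a saturated
structural image) cannot be rescaled and is returned unchanged with a logged
warning so cohort runs survive pathological inputs.

A property worth knowing: because the structural image is *inverted* before
multiplying, structural noise is amplified wherever the structural signal is
bright (small `I_max − s`). With realistic structural SNR this is negligible;
with angiogram-level noise on the structural image it becomes the dominant
FD% bias. See "Phantom intensity model" below.

## Ring ROIs

The exact Euclidean distance transform is computed from the filled
MNV ∪ halo region (pixel centers, 0-based indices, distances
center-to-center, in pixel units × pitch). Ring *k* is the half-open band
`(k−1)·w < d ≤ k·w` with `w = 200 µm` and `n = 5` rings by default, so the
rings exactly partition the 1000-µm band and never overlap the lesion (the
halo itself is excluded from analysis by construction). For a simply
connected halo, the distance map from the filled region and from its outer
contour coincide; we use the filled region. Rings reaching the scan border
are clipped with a warning; a ring with no on-grid pixels is an error. Eyes
whose MNV comes closer than 1 mm (configurable) to a scan border are
rejected, mirroring the acquisition inclusion rule. Per-ring analysis masks
subtract the vessel mask; a ring whose effective area falls below a floor
(default 100 px) is flagged and dropped pairwise from cohort statistics
rather than zeroed. The T1 ring configuration is transferred unchanged to T2
(inputs are assumed co-registered; no registration is attempted).

## Binarization

Phansalkar local adaptive thresholding,
`t = m·(1 + p·e^(−q·m) + k·(s/r − 1))`, over a circular window of radius
15 px on intensities normalized to [0, 1] by the bit-depth maximum, with the
standard constants (k, r, p, q) = (0.25, 0.5, 2.0, 10.0) of the common
auto-local-threshold implementation — only the radius is prescribed by the CC
OCTA literature; the rest are the de facto defaults. Window statistics use
mirror (edge-repeating) padding, `s` is the population standard deviation,
and a pixel is FLOW iff its value is strictly above `t` (so a uniformly zero
image is all-deficit). Deficits are the complement of the bright flow phase.
The whole image is thresholded once and ROIs are applied afterwards, so
window statistics never depend on ROI shape. The production path computes
window sums by FFT convolution with the disc footprint; the suite verifies it
pixel-for-pixel (|Δt| < 1e−9) against a naive double-loop evaluation.

## Per-ring metrics

Deficits are labeled with 8-connectivity (configurable) on the deficit map
clipped to each ring's effective mask: a deficit straddling two rings counts
in each ring with only its in-ring pixels, which makes per-ring deficit areas
sum exactly to the area in the union band. Per ring: FD% = 100 × deficit
pixels / effective ring pixels; FDn = number of labeled particles; FDa = mean
particle area. FDa is reported in µm² (pitch-aware) because unitless particle
areas are ambiguous across devices; pixel counts remain available. No
minimum-particle-size filter is applied by default (`min_fd_area_um2` exists
for sensitivity analyses). Lesion areas are pixel counts × pitch², in mm².

## Statistics

CC metrics from binarized counts are not normally distributed; variables are
screened with Shapiro–Wilk (3 ≤ n ≤ 5000) and visits are compared with the
Friedman test, retained even at k = 2 visits for fidelity to the study design
it reproduces (at k = 2 it reduces to a sign-type test; this costs power
against Wilcoxon but matches the published method). Within-eye midranks with
the standard tie correction `C = 1 − Σ(t³−t)/(n·k·(k²−1))` feed the χ²
approximation with df = k − 1; fully tied tables return χ² = 0, p = 1. The
empirical type-I error at n = 30, k = 2 is ~0.043 (the sign-test
discreteness), verified on 400 null cohorts. No multiple-testing correction
is applied across the 15 ring × metric tests by default (a Holm option
exists, off by default). Inter-grader agreement uses ICC(3,1) — two-way
mixed-effects, consistency, single rater — from ANOVA mean squares,
`(MS_S − MS_E)/(MS_S + (k−1)·MS_E)`, with the F-based 95% CI; "two-way
mixed-effects" admits several flavors and this single-rater consistency form
is our documented choice for two-grader area agreement.

## Phantom design

The generator emulates the study's inputs with controllable ground truth.

**Geometry.** Centered MNV disc (default radius 250 µm) and halo annulus
(default width 250 µm) on the 3 × 3 mm grid; the constraints are (i) MNV
margin: `mnv_radius + 1000 µm ≤ half extent` and (ii) rings fit:
`mnv_radius + halo_width + n·200 µm ≤ half extent` (the outermost ring may
clip at the grid corners, which for the default geometry costs < 0.1% of its
area). Vessels are vertical stripes (default two, 36 µm wide) that attenuate
both images multiplicatively by `shadow_strength`.

**Deficit placement.** Deficits are random discs (areas around
`deficit_mean_area_um2`, default 360 µm²) stamped zone by zone — five ring
bands plus the background — until the zone's deficit pixel count equals
`round(fraction × zone area)` exactly, trimming the final blob's outermost
pixels. Placement keeps a 1-px eroded gap inside each zone so deficits never
8-connect across zone boundaries: per-ring truth (realized fraction,
particle count) is then exact and independent. Default T1 ring fractions
(0.5248, 0.5137, 0.5030, 0.4922, 0.4828) follow the reported pre-treatment
FD% gradient — highest adjacent to the halo — with 0.45 in the far
background. Realized fractions are recorded in the truth sidecar and are the
oracle for every measurement test. The phantom does not attempt the reported
*absolute* per-ring particle counts (thousands), whose scale depends on
unstated size filtering; relative T1/T2 behavior is the target.

**Intensity model.** Flow ~102, deficit ~31, MNV ~115, halo ~26, structural
~168 on the 8-bit scale, with multiplicative lognormal speckle (σ = 0.1 on
the angiogram, σ = 0.03 on the structural slab — structural en face images
are volume-averaged and much cleaner than decorrelation angiograms). These
levels were fixed at design time so that (a) Phansalkar sees bright objects
with local contrast, its operating assumption; (b) a 50% shadow pushes
uncompensated flow pixels across the local threshold (the artifact
compensation exists to fix — with a brighter background, Phansalkar's
locality would itself hide the shadow and the compensation stage would be
untestable); and (c) the structural level ≈ 2/3 of range makes the
inverse-multiply model cancel a 50% attenuation almost exactly. The MNV level
is kept moderate so the post-compensation min–max rescale is not stretched by
bright-outlier speckle, which would push normalized flow into the steep
`e^(−q·m)` region of the threshold curve.

**Paired cohorts.** Each eye's T2 reuses its T1 geometry and masks ("same
size and position"). The T2 deficit mask is the T1 mask fragmented by
`split_factor` — each component is cut by removing a one-pixel separating
line at coordinate quantiles perpendicular to its longer bounding-box axis,
so the expected component count scales by the factor — and then adjusted zone
by zone to the target fraction `T1 realized + (delta + N(0, sd))/100`
(clamped to [0, 1] with a warning), by removing whole components or adding
blobs. Adjusting *after* splitting restores the separator pixel loss, so
total deficit area per ring is conserved to < 1% under a pure split. Default
deltas (−2.02, −3.07, −3.57, −3.45, −3.18 percentage points) are the reported
T1→T2 per-ring FD% differences; the default split factor 1.25 is the mean of
the reported per-ring FDn T2/T1 ratios; eye-level noise is N(0, 2 points)
per eye and ring. Per-eye seeds derive from `SeedSequence([cohort_seed,
eye_index])`; rendering noise lives on a separate derived stream so the truth
configuration is identical whether or not images are synthesized. T2 speckle
is redrawn (an independent acquisition); T1 baseline fractions are shared
across eyes — between-eye baseline variance is *not* modeled, so cohort T1
SDs are much smaller than clinical ones; paired tests are unaffected.

**What the phantom does not emulate.** Physical OCT speckle statistics,
motion/projection artifacts beyond multiplicative stripes, eye-level baseline
heterogeneity, lesion growth or halo shape change between visits, and
absolute FDn scale. Passing tests therefore demonstrate correctness of the
measurement chain and statistics under a controlled generative model — not
clinical performance on device images.

## Replicated longitudinal study

The directional study generates 30-eye cohorts under the default reperfusion
design, measures metrics in ground-truth-mask mode (rings from each eye's
masks, vessel exclusions applied; binarization bypassed — its accuracy is
established separately), and checks the reported signature: Friedman
p < 0.05 for FD% in R2–R5 and for FDa and FDn in all five rings, with
mean FD% and FDa lower and mean FDn higher at T2. The study uses the full
500 × 500 geometry with 1440 µm² mean deficit size (≈ 40 px) so per-ring
particle counts (≈ 40–140) resolve the fragmentation mechanism; it is
replicated 100 times with fresh seeds (≈ 4 s per cohort), and ≥ 95
replications must reproduce the pattern. R1 is exempted from the FD%
significance requirement by design: its delta (−2.02) is the smallest against
the same eye-level noise, mirroring the reported borderline R1 result.

## Numerical choices and degenerate inputs

- Ring bands are half-open `((k−1)w, kw]`, making rings a partition; ties in
  distance cannot double-assign pixels.
- Threshold comparison is strict (`value > t`); constant images yield a
  single global threshold and an all-flow or all-deficit map with a warning.
- FFT window sums run in float64; agreement with exact summation is ~1e−12,
  against a 1e−9 test tolerance.
- Component connectivity is 8 by default (4 available); FDa of an empty ring
  is 0 by convention, while *flagged* rings (effective area below floor)
  propagate NaN and are dropped pairwise in cohort tables.
- Empty MNV or halo masks: margins and rings are errors (undefined anchor);
  lesion areas degrade to 0 with a warning.
- `split_deficits` leaves components narrower than 3 px along both axes
  intact; separator loss is `≈ 1/width` of a component's area, so the
  area-conservation claims hold for components tens of pixels and larger.
- Blob placement falls back to single free pixels only when a zone is nearly
  saturated (fractions → 1), preserving exact realized fractions.

## Known limitations

- With two visits the Friedman test is a sign-type test: it discards
  magnitude information and its size at n = 30 is 0.043, not 0.05.
- The compensation model is strictly multiplicative; additive haze or
  saturation is not corrected and not simulated.
- Phansalkar constants beyond the radius are fixed to the reference defaults;
  devices calibrated differently may need `PhansalkarParams` overrides.
- The phantom's exact-fraction placement makes T1 between-eye variance
  artificially small; effect-size calibration against clinical SDs should use
  the paired deltas, not the T1 cross-sectional spread.
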