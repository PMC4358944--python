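# Methods

This note records the models behind `airwayquant`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical conventions that are pinned so results are reproducible.

## Measurement chain

The pipeline mirrors how airway vitronectin expression is quantified in
practice. Dual-channel confocal z-stacks (8-bit, (z, y, x) indexed) are
thresholded per channel and summarised by Pearson's R_p and Manders
M_G/M_R. Stained 2-D sections arrive as categorical label maps
(background / tissue / gland / positive-gland / epithelium /
positive-epithelium; the "positive" codes are refinements of their parent
compartment) and are quantified by point-grid stereology and pixel-exact
areas. Western blots are reduced to lane profiles and loading-controlled
band ratios. All per-image values are reduced to subject medians before any
group test, so the subject — not the image — is the unit of analysis.

## Background threshold

The threshold of a channel is `mean + 2·SD` of the voxel intensities over
the analysed region, with the *population* SD (ddof = 0) and a strictly-
greater-than comparison. The population/sample distinction is irrelevant at
10⁶ voxels but is pinned so small-fixture tests are exact. Under a Gaussian
background this retains the upper one-sided 2-SD tail, ≈ 2.28% of
background voxels — a calibration the acceptance suite checks directly on
continuous Gaussian fields (8-bit quantization would distort the tail of an
integer-valued field; the rule itself is agnostic to dtype). The threshold
is computed per channel per stack; thresholds can also be supplied
explicitly wherever they are consumed.

## Colocalization

R_p is computed on unthresholded intensities (it is invariant to affine
detector settings, a property asserted numerically to 1e-12), optionally
within a region of interest; a constant channel raises an explicit
"undefined correlation" error rather than returning NaN. Manders
coefficients follow the standard thresholded M1/M2 convention: a voxel
contributes its green intensity to the M_G numerator when green exceeds the
green threshold *and* red exceeds the red threshold; the denominator is the
channel's total above-threshold intensity in the same region. With that
convention both coefficients are bounded in [0, 1] and, on synthetic stacks
with uniform object brightness, M_G estimates the colocalized fraction of
the green structure — the basis of the recovery tests.

## Stereology

The 81-point grid is a 9 × 9 systematic tiling; each point sits at its tile
centre, and in systematic-uniform-random mode one shared offset per grid is
drawn uniformly within a tile. Points live in continuous pixel coordinates
and take the class of the pixel containing them (floor of the coordinate);
there is no fractional counting at boundaries. Because every pixel is
equally likely under the random offset, the point-count fraction is an
unbiased estimator of the area fraction; the acceptance suite verifies bias
≤ 0.01 over 10⁴ offsets and that estimator variance falls as the grid
densifies (81 → 324 → 1296 points). G_vf uses points on any non-background
class as its denominator; V_vf uses gland points. Zero denominators yield
missing values (with a warning), never silent zeros, since a section without
glands carries no information about the within-gland fraction. V_vf is a
ratio of correlated counts and therefore not exactly unbiased; with ≥ 30
gland hits per 81-point grid the ratio bias is far below the 0.01 tolerance.

## Densitometry

Lane profiles are per-row means across the lane width, inverted when bands
are dark-on-light. Band volume is the profile sum above the straight line
joining the integration window's endpoint samples, clipped below at zero;
windows are explicit inputs (± 4 σ around each band in the synthetic
studies), not auto-detected. The single-sample endpoints make individual
volumes sensitive to noise at those two samples (≈ w/√2 intensity units of
baseline error for window width w), so ratio-recovery checks average
replicates; with the default noise this recovers abundance ratios across a
16-fold range to well within 10%. β-actin normalisation cancels loading and
exposure scale by construction.

## Cohort statistics

Kruskal–Wallis uses midrank ties and the standard correction
`1 − Σ(t³−t)/(N³−N)`, with a χ² (k−1 df) p-value; scipy provides the
computation behind the module surface, and brute-force rank oracles verify
it exactly on small instances. Dunn's post test uses the pooled-rank z
statistic with tie term `Σ(t³−t)/(12(N−1))` and Bonferroni correction over
all pairs (adjustment configurable; `"none"` gives raw p-values).
D'Agostino–Pearson K² requires n ≥ 8 (the transformed-moment
approximations are unreliable below that) and rejects zero-variance input.
The two-group comparison is the pooled-variance t-test with
df = n_a + n_b − 2. Quartiles everywhere use linear interpolation, and
summaries print as median (Q1–Q3). No covariate adjustment (e.g. for age)
is offered: the test layer compares groups exactly as designed.

## Synthetic data

The generators define the study conditions and are first-class, tested code.

*Confocal stacks.* Green objects are ellipsoids with lognormal semi-axes
(median 4 voxels, σ = 0.25) placed uniformly inside the volume (overlap
allowed; an overcrowded specification raises after bounded retries). A
target fraction of green-object voxels — selected blob-by-blob, with a
coherent sub-slab of one boundary blob to hit the count exactly — also
carries red signal. Colocalization is defined on these pre-blur masks, and
the realized (post-selection) fraction is the reference truth. Both
channels are blurred with an isotropic Gaussian PSF approximation
(σ = 0.7 voxels by default), degraded with Poisson shot noise plus Gaussian
read noise (SD 2), and quantized to 8-bit. Defaults: background 8,
signal 180, voxel size (0.3, 0.116, 0.116) μm.

*Sections.* Compartments are carved from smoothed Gaussian random fields by
exact top-k selection, so realized fractions are pixel-exact (within half a
pixel of target) while shapes stay organic. Nesting: background
(default 12%), then gland within tissue, positive within gland, epithelium
within non-gland tissue. A positive target that rounds to zero pixels
realises as zero; only a request against an empty parent compartment (e.g.
epithelium when all tissue is gland) is an unreachable-target error.

*Cohorts.* The default design is 14 control / 7 asthma / 10 COPD subjects
with 1 + Poisson(4) images each (mean 5; real studies vary per subject, so
a count distribution is exposed rather than a constant). Subject true
positive fractions are Beta(μ·κ, (1−μ)·κ) draws with group means
0.29 / 0.07 / 0.04 and concentration κ = 30 — the ratio structure of a
strong disease effect on V_vf with no effect on gland geometry (gland share
mean 0.39 for all groups). Each image's gland share and positive fraction
are themselves beta draws around these values (κ = 50 and 200), giving the
section-to-section variability real microscopic fields show.

*Gels.* Bands are Gaussian peaks whose integral is abundance × 1000
intensity units (σ = 4 samples), on a baseline of 5 with a slow sinusoidal
drift (amplitude 2) and white noise (SD 1). Within-lane band overlap
(centres closer than four combined sigmas) is rejected at specification
time.

What the generators do **not** emulate: measured point-spread functions,
chromatic shift or channel cross-talk, histological texture and staining
chemistry variability, lane smearing or molecular-weight calibration.
Passing recovery tests therefore demonstrates correctness of the
measurement chain under controlled conditions, not robustness to every
artefact of real acquisitions.

## Problem sizes

Validation runs use deliberately modest sizes chosen to exercise the full
chain: colocalization recovery on 12 × 48 × 48 stacks (20 replicates per
level), threshold calibration on 10⁶ voxels, stereology bias on a 512²
section with 10⁴ grid offsets, test calibration on 2000 simulated cohorts,
and end-to-end power on 200 replicate studies with 96 × 96 sections. The
point-grid estimator — not image resolution — dominates the sampling noise
of volume fractions, so section size does not materially affect the power
results.

## Determinism

Every stochastic component takes an explicit seed (`numpy` `default_rng`;
no global state). A study config plus seed determines every output file
byte-for-byte, and the quantification stages never see group labels —
labels join the data only in the statistics layer, the computational
analogue of observer blinding.

## Known limitations

- Manders denominators are above-threshold sums; analyses that want the
  unthresholded total-intensity denominator must pass thresholds of −1.
- The stereology layer is 2-D; volume fractions rely on the usual
  sections-as-samples argument and no 3-D grid is provided.
- Band windows are user-supplied; there is no automatic peak detection.
- Costes-style randomisation p-values and object-based colocalization are
  out of scope.
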