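# Methods

`ctcemt` implements a single-cell immunofluorescence quantification and
EMT-scoring workflow for circulating tumor cells (CTCs): per-cell Corrected
Total Cell Fluorescence (CTCF) measurement on multi-channel cytospin images,
bead-based linearity calibration of the detector, the vimentin/keratin
(vim/K) EMT index with reference-cell-line cut-offs, and the high/low-keratin
(HK/LK) median-split patient stratification with group-comparison and
survival summaries. Every stage is exercised end to end on synthetic inputs
whose statistical structure is generated by the package itself.

## Quantification model

For a segmented cell region R in channel c,

    CTCF(R, c) = sum of pixel intensities over R  -  |R| * b_c

where `b_c` is the mean background of channel c, estimated by default as the
median intensity over all pixels outside every segmented region (a box-based
estimator emulating manual background boxes is available). The
background-corrected mean intensity is `CTCF / |R|`. Negative CTCF values
are data (a region dimmer than background), never clipped; they propagate and
are only clamped to zero at the ratio stage, where a negative marker level
has no biological reading.

Segmentation is nucleus-seeded: Otsu threshold on the DAPI channel,
8-connected components, then dilation of each nucleus by a fixed margin
(default 5 px) with overlaps resolved by nearest-nucleus assignment
(`skimage.segmentation.expand_labels`), so regions are always disjoint and
CTCF is additive over region splits. Regions outside
`[min_cell_area, max_cell_area]` (defaults 50–5000 px) are discarded. The
whole dilated region is measured for every channel; cytoplasm-only masks are
not attempted.

CTC identity is DAPI-positive AND CD45-negative. DAPI positivity requires a
raw region mean above `dapi_positivity_factor` × background; the default 1.5
is deliberately below nucleus-only contrast because the nuclear signal is
diluted over the dilated whole-cell region. CD45 negativity uses a two-class
(k-means) split of region CD45 levels; a cell is negative when it falls in
the dim class, below the 5th percentile of the bright class, and near
background in absolute terms. The absolute guard matters in two degenerate
regimes: a slide of pure PBMCs (k-means will still split a unimodal bright
population) and a slide of pure CTCs. When the two classes are not clearly
separated (center gap below 4 within-class SDs) the rule falls back to the
absolute threshold alone and logs a warning. Keratin is a measurement, not a
gate: keratin-negative, vimentin-only CTCs are retained.

## Calibration

Beads of nominal relative intensity 100/33/10/3% imaged at PMT voltages
450–600 V give one unweighted OLS fit of measured vs nominal level per
voltage (replicates enter as points). The system is "linear up to" the
highest voltage V such that every fit at or below V has R² ≥ `r2_min`
(default 0.99); the threshold is a package choice of criterion for
"practically linear". `check_in_range` then reports what fraction of cell
mean intensities lie inside the measured bead limits at the working voltage,
the standard sanity check that cellular signals sit on the standard curve.

## EMT index

Per cell, the index is the ratio of background-corrected mean intensities,
vim/K by default but generic over marker pairs (vimentin/EpCAM,
fibronectin/K run through the same path). Cut-offs come from reference
distributions: `epithelial_upper` = max ratio of an epithelial reference
line, and the mesenchymal band = [min, max] of a mesenchymal reference line.
With the bundled MCF-7 and Hs578T reference profiles this yields 0.49 and
[5.47, 38.88]. Classification: epithelial if ratio ≤ `epithelial_upper`
(the boundary value is epithelial — "up to" includes its endpoint, which
also makes the three classes a partition), mesenchymal if ratio ≥
`mesenchymal_lower` (values beyond `mesenchymal_upper` are classified
mesenchymal with a QC flag rather than rejected), intermediate otherwise.
Ratios are undefined when the denominator mean intensity falls below a floor
(default 1% of the epithelial reference median keratin); undefined cells are
excluded from classification and counted in the summary's QC column.

## Cohort stratification

All CTC keratin values in a cohort are pooled; each CTC is "high" iff
strictly above the pooled median; a patient is HK iff more than 50% of their
CTCs are high, else LK. Two deliberate choices close gaps the verbal rule
leaves open: values exactly at the median are not high, and a patient with
exactly half high CTCs is LK — both follow from reading "more than 50%"
strictly, and together they make HK/LK a partition invariant to patient and
CTC ordering. The keratin values entering the split are total CTCF (not
per-area), matching image-gallery-style readouts.

Group comparisons: pooled per-CTC keratin between two patient strata by
pooled-variance t-test with a two-sided variance-ratio F-test reported
alongside; HK/LK vs a binary covariate by Pearson chi-squared on the 2×2
table without continuity correction (the conventional reading of a
"correlation" between two binary percentages); patients with unknown
receptor status are excluded listwise and counted. Survival: Kaplan–Meier
per stratum with Greenwood standard errors, S(12 months) reported, and a
log-rank test between strata. Three or more cell populations are compared by
Kruskal–Wallis with Dunn's post test (mean ranks, tie-corrected variance,
Bonferroni adjustment — the adjustment is unnamed in common practice, so
the most conservative standard one is used). Cox regression is out of scope.

## Synthetic data

The generators define the study conditions the tests assume; all are
deterministic under their seed.

**Beads.** Full-scale response grows exponentially with voltage
(`gain_per_volt`, default 0.02/V). At or below `saturation_voltage` (default
560 V) the measured intensity is exactly proportional to nominal level;
above it the response soft-clips toward the full-scale-at-saturation
ceiling, `y = C(1 - exp(-x/C))`, so the brightest beads compress and R²
degrades at 600 V while 450–550 V stay linear. Measurement noise is
multiplicative Gaussian with CV 0.03, a typical bead-replicate spread, small
enough that sub-saturation R² stays above 0.99 with wide margin.

**Reference cells.** Marker levels are positive and right-skewed, so the
marginals are lognormal and the keratin–vimentin dependence is a Gaussian
copula; cells whose vim/K falls outside the profile's `ratio_range` are
rejected and redrawn (cap 1000 attempts per cell, exceeding it is an error,
never silent truncation). The bundled profiles carry the published marginal
mean/SD, ratio range and ratio mean/SD of MCF-7, T47D, MDA.MB231, Hs578T,
EGF-treated MCF-7 and pooled patient CTCs. Because those statistics describe
the observed (in-range) cells, naive moment matching followed by rejection
would bias the output: the sampler therefore solves the closed-form
truncated-moment equations (tilted-measure identities under the
lognormal/copula model) for pre-rejection parameters — including the copula
correlation, initialized from the profile's ratio SD and softly penalized
toward it and toward acceptance rates above ~5% — so that the generated
cells reproduce the profile marginals and, implicitly, the reported ratio
statistics. For user profiles without a ratio constraint the correlation
defaults to −0.3 (a mild EMT trade-off within a line; the within-line
correlation is unknown and exposed as a parameter, never asserted). T47D's
published ratio range is tighter than any lognormal consistent with its
marginals, so its calibrated fit trades ratio-SD fidelity for marginal
fidelity; its marginal means/SDs still verify within Monte-Carlo tolerance.

**Cytospin images.** Cells are discs (radius 7–10 px) with concentric
nuclei (0.7× radius) on a constant background (100) in 16-bit range, edges
Gaussian-blurred (σ = 1 px, which conserves channel totals away from
borders), plus Gaussian read noise (SD 3). CTCs carry keratin/vimentin from
a cell-line profile and no CD45; PBMCs carry CD45 and vimentin and no
keratin; all cells are DAPI-positive. Placement enforces a pairwise center
distance of twice the maximum radius plus 1 px and a border margin, with a
bounded number of attempts. The ground-truth table records each planted
cell's center, radius, identity, and exact pre-blur channel totals. The
geometry is deliberately simple — no point-spread function, chromatic
effects, autofluorescence spectra, or irregular morphology — sufficient to
test quantification arithmetic and identity rules, not segmentation of
realistic micrographs; passing these fixtures says nothing about performance
on real images with touching or irregular cells.

**Cohorts.** Default 61 patients, each with 2–60 CTCs; triple-negative
status drawn at 18% prevalence; per-CTC keratin lognormal with mean 122.4
(TN) or 175.0 (non-TN) and common SD 115 — between the two reported group
SDs, as the generator has one dispersion knob. Non-TN patients redraw
receptor statuses until at least one is positive. Survival is exponential
with the rate solved from the target 1-year OS of the patient's keratin
stratum (defaults 0.733 HK / 0.462 LK), censored uniformly on
(0, 36] months. The HK/LK stratum that drives survival is assigned inside
the generator with the same strict-majority rule the analysis applies, so
recovering the per-stratum OS downstream is a genuine round trip. Only the
direction and approximate size of these effects are emulated; the cohort's
published percentages and p-values derive from unreleased patient data and
are not reproduction targets.

## Numerical choices and edge cases

- Constant bead response across levels yields slope 0, R² 0 rather than an
  error; fewer than two distinct levels at a voltage is an error naming it.
- A blank image segments to zero regions (not an error); regions covering
  the whole image make background estimation an error.
- Degenerate two-group t-tests (zero variance in both groups) return
  t = 0, p = 1 when means agree.
- Overlapping reference ratio distributions make cut-off derivation an
  error: the scheme is undefined there.
- CSV outputs carry no timestamps and all randomness flows from a single
  seed, so re-runs are byte-identical; every output has a JSON sidecar with
  seed and config hash.

## Problem sizes

Bundled checks use 20 cytospin fixtures of 13 cells, reference samples of
500–1000 cells, and cohorts of 200–400 patients; Monte-Carlo assertions use
3–4 standard-error bands at those sizes.
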