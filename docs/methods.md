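# Methods

This note documents the generative model, the measurement and statistical
procedures, the defaults and why they were chosen, and what the synthetic
validation does and does not establish about real microscopy data.

## Synthetic donor cohorts

Each donor is a latent trait vector: mean cell area, cell width/length
ratio, mean nucleus area, nucleus width/length ratio, and a cytoskeletal
filament-density factor. Areas are log-normal and ratios logit-normal, so
support constraints (areas > 0, ratios in (0, 1]) hold by construction;
the spreads (cell area median 8,000 µm², SD(log) 0.35; nucleus w/l mean
0.72, SD(logit) 0.35) are set to produce the wide inter-donor histograms
characteristic of subconfluent primary BM-MSC cultures. Cell and nucleus
area latents are coupled at r = 0.5 (bigger cells carry bigger nuclei);
all other trait latents are independent.

**Effect planting by Gaussian copula.** Every trait and every outcome is a
strictly monotone transform of a standard-normal latent. A target Spearman
correlation r_s between a trait and an outcome is planted by giving their
latents Pearson correlation ρ = 2·sin(π·r_s/6), the exact bivariate-normal
identity; because all marginal transforms are monotone and the downstream
screen is rank-based, the target survives the transforms unchanged.
Default effects: nucleus w/l → osteogenic outcome r_s = −0.5; cell area →
proliferation AUC r_s = −0.5; nucleus w/l → CD146+ % r_s = −0.5. All other
trait–outcome pairs are independent (in particular the adipogenic outcome,
which serves as the built-in null). Configurations whose combined loadings
would leave an outcome with non-positive residual variance are rejected.

**Assay panels.** Growth is logistic from 1,000 seeded cells toward a
4×10⁵-cell capacity; the donor's true doubling time is log-normal with
cohort mean 76.5 h (SD(log) 0.35), tied monotonically to the proliferation
latent. Counts at days 1, 3, 6, 9, 12, 15 come in triplicate with
multiplicative log-normal noise (CV 10% — the triplicate design reports no
error model, so a typical hemocytometer CV is assumed). The osteogenic
outcome is alizarin intensity 50 ± 20 AU; the adipogenic outcome is
log-normal lipid area (median 8%), strictly positive and hence
log-transformable; ALP activity is log-normal around 0.4 AU; CD-marker
percentages use the reference cohort means/SDs (CD44 99.87 ± 0.21 through
CD146 62 ± 30 and CD271 26 ± 25), clipped to [0, 100].

**Donor feature table (fast path).** The table generator bypasses
rendering: donor-mean features are the latent traits plus the sampling
error of averaging `cells_per_donor` cells; derived geometry summaries
(width, length, roundness) follow from the equivalent-ellipse relations
with additional donor-level dispersion (SD(log) 0.08, roundness 0.12),
which keeps them informative but not collinear with the primary traits —
mirroring how correlated but distinct summaries behave in real feature
sets. SER texture summaries load on per-channel texture latents (tubulin
ridge/edge on the filament-density factor at 0.6; everything else weakly
at 0.2). Predictors for the multivariable analysis are the 36 donor-mean
columns; within-donor SD columns are carried in the table as dispersion
metadata but are not morphology predictors.

## Field rendering

Cells are smoothed convex blobs: a rotated ellipse of the sampled area and
axis ratio, perturbed by low-order radial harmonics (amplitude 0.06) and
rescaled to the target polygon area. Placement is dart-throwing with a
3 px clearance and bounded retries; overlap is excluded because the
emulated cultures are subconfluent, and an unplaceable request raises an
error rather than silently rendering fewer cells. Nuclei are interior
ellipses sharing the cell's orientation. The DAPI channel is the nucleus
mask at intensity 0.8; actin/tubulin channels are a dim cytoplasmic fill
(0.25) plus anti-aliased filament strokes whose count scales with the
donor's filament-density factor, all blurred at σ = 1 px with a smooth
background gradient (amplitude 0.05) and Gaussian noise (SD 0.02). Ground
truth records the label maps and per-object pixel-exact areas and
equivalent-ellipse axes. Rendering is bit-deterministic in (donor, seed,
field index).

## Segmentation

Nuclei: Gaussian smooth (σ = 1), large-scale background subtraction
(σ = 50), Otsu threshold, hole filling, removal of objects under 30 px
(sub-nuclear debris at ~1 µm/px), then a distance-transform watershed
(seed separation 8 px) to split touching nuclei. Cells: seeded watershed
on the smoothed cytoskeleton channel restricted to a foreground mask; the
foreground threshold is Otsu relaxed by a factor 0.5 because the bright
filament class biases the between-class cut upward relative to the dim
cytoplasmic fill — the relaxed cut lands near the fill's half-intensity,
where the blurred boundary crosses the true edge (validated against
ground truth: mean area error +0.6%, 98% of cells within 5%). Every cell
inherits its seed nucleus id, contains its nucleus by construction, and
objects touching any image edge are removed from both maps before
analysis. Label maps are 4-connected with background 0. The µm/px scale is
configuration, never hard-coded.

## Features

Width and length are the minor/major full axis lengths of the
second-moment equivalent ellipse (rotation invariant, unlike bounding
boxes); w/l ∈ (0, 1]; roundness = 4·area/(π·length²) — one of several
conventions in use, fixed and documented here. SER responses are built
from γ-normalized Gaussian derivatives at σ = scale (default 1 px):
Hessian eigenvalues λ1 ≤ λ2 classify spot (both negative), hole (both
positive), ridge (λ1 ≪ 0, |λ2| small), valley (λ2 ≫ 0), saddle
(λ1 < 0 < λ2); edge is the gradient magnitude; bright/dark compare
intensity to the region mean. Each non-negative raw response R is
normalized per region as R/(R + S) with S the region's intensity SD,
making every feature dimensionless in [0, 1), exactly invariant to
intensity rescaling, and zero on (numerically) constant regions; the
feature is the mean over the mask. DAPI texture is computed over the
nucleus mask, actin/tubulin texture over the cell mask. The texture
family's vendor implementation names nine patterns but enumerates eight
tokens; the eight are implemented and the pattern list is configurable
rather than guessing a ninth. Acceptance of the texture features is by
orderings and invariances (lines score ridge > blobs, blobs score spot >
lines, exact 90° rotation invariance), not by equality with any
proprietary implementation.

Donor profiles aggregate mean, SD, and CV per feature; donors under the
cell minimum (default 1,000, relaxed in smoke-scale runs) are flagged,
never silently dropped; CV is reported only for positive means.

## Statistics

**Spearman.** Midrank ties; two-tailed p by the t approximation, replaced
by exact enumeration of all permutations for n ≤ 9.

**ROUT.** The scatter is fitted by a robust straight line (IRLS with
Lorentzian weights w = 1/(1 + (res/RSDR)²)); the straight line is the
minimal special case of the robust-nonlinear-regression family and the
appropriate baseline for correlation scatters. The RSDR is the 68.27th
percentile of |residuals| scaled by n/(n−K), K = 2. Residual/RSDR maps to
a two-tailed t p-value (df = n−K), and a step-up false-discovery schedule
flags outliers: the j-th largest residual is tested at (Q/100)·j/n and the
largest passing j flags itself and all larger residuals. Q = 1% by
default; Q = 0 disables removal. Measured operating characteristics at
n = 50: clean data keep all points in ~98% of replicates (≤1 removal in
>99%); five 10σ contaminants are all removed in >99% of replicates.

**ROC.** Mann–Whitney midrank AUC; DeLong variance for the CI (default
level 97.5%, kept because that is the convention of the reference
analysis). The result carries the raw AUC (whose null expectation is 0.5 —
required for calibration checks) alongside an oriented value ≥ 0.5 with a
direction flag.

**Stability selection.** Subsamples of size ⌊n/2⌋ without replacement (the
method's standard); predictors standardized within each subsample to
avoid leakage across subsamples; per subsample the first q distinct
variables to attain nonzero coefficients along the Lasso path (LARS
traversal from the fully penalized end) — the "predetermined number of
explanatory variables" reading; simultaneous entries are broken toward the
lower column index and logged. q is derived from the error bound
q²/((2θ−1)p) ≤ PFER unless overridden. The defining guarantee — expected
false stable selections ≤ PFER under a global null — is verified by
simulation (n = 56, p = 40: mean stable-set size ≈ 0.15, far under the
budget of 2). The AIC ladder uses OLS with AIC = n·ln(RSS/n) + 2k
(constants omitted identically across models, so differences are exact);
collinear covariate sets fit through the pseudoinverse with a warning; the
adipogenic outcome is log-transformed before fitting.

## Problem sizes used in validation

The automated checks run at desk scale: 500 replicates for ROC and ROUT
calibration, 200 replicates for PFER control and correlation-screen
recovery, 100 end-to-end feature-table runs for selection power, and an
8-field rendered cohort (~60 cells) for the imaging oracle. These sizes
give Monte-Carlo standard errors comfortably below the tolerances tested.

## What the synthetic validation shows — and what it does not

Passing tests establish that the implementation recovers planted effects
of the magnitudes reported for the reference cohort (|r_s| ≈ 0.5 at
n = 56), controls its stated error rates, and measures geometry faithfully
on clean, subconfluent, non-overlapping cells. The renderer deliberately
omits point-spread physics, uneven illumination beyond a linear gradient,
confluent cell contact, debris, and staining artifacts; real Operetta-like
data will stress segmentation in ways these fixtures do not, and the
morphology conventions here (equivalent-ellipse axes, the roundness
definition, documented SER normalizations) are contract-level stand-ins
for unpublished vendor definitions. Cohort-specific numbers from any real
study (particular r_s values, the AUC of a particular contrast) depend on
that cohort's data and are not reproduction targets; the calibration
quantities (null AUC = 0.5, PFER ≤ 2) are.

## Known limitations

Binary (logistic) outcomes, complementary-pairs stability selection,
elastic-net selectors, 3-D segmentation, and multiple-testing correction
across the bivariate screen are out of scope; the screen reproduces the
reference behavior of reporting unadjusted correlations (an optional FDR
column can be added downstream but is deliberately not the default). The
alizarin and lipid quantifiers are simple monotone estimators validated on
fixtures; they do not attempt colorimetric calibration.
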