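# Methods

This note documents the models, numerical choices and known limits of the
package. It describes what the code computes and why each default is what
it is; all quantitative claims here are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## Tissue model and segmentation

A synthetic core is a square 8-bit multi-channel image of elliptical
glands on a dark stromal background. Glands are rendered with hard edges
(no anti-aliasing) so that zero-noise segmentation has an exact
pixel-level answer; ellipses are placed by rejection sampling with a
non-overlap guarantee. All glands carry panCK; benign glands carry KRT5
over their whole area (an optional brighter basal rim is available via
`krt5_ring_boost`, off by default) so that the ground-truth label raster
{0 stroma, 1 benign/KRT5+, 2 cancer} coincides with what the mask algebra
epithelium = panCK+, krt5_pos = panCK+∧KRT5+, cancer = panCK+∧KRT5−,
stroma = ¬epithelium recovers. A rim-only KRT5 pattern would make benign
gland interiors panCK+/KRT5− and contradict those labels.

Thresholding defaults to Otsu with a fixed-value override. Masks use the
convention value ≥ threshold; because the classic Otsu cut marks
foreground as value *>* cut, the returned threshold is moved to the
midpoint between the cut and the next observed value above it. On clean
two-valued images this makes `mask == foreground` exact; on continuous
images the difference is below the intensity quantisation.

Object detection is a Euclidean-distance-transform watershed seeded at
local maxima with a minimum seed separation of 5 px, followed by a strict
particle filter (area > 100 px retained). Cells in screen images are
labelled by nucleus detection (Hoechst threshold + watershed) and
fixed-radius label expansion (default 5 px); contested pixels go to the
nearest nucleus, so cell regions partition the image.

## Intensity quantification

α is the plain mean over all masked pixels, zeros included: the read-out
is total intensity over total area, and excluding zeros would leave α
undefined on dark regions. α is permutation-invariant and satisfies the
area-weighted union property, both asserted in tests. Patient-level scores
are unweighted means over cancer cores (cores, not pixels, are the unit of
aggregation), with a ≥ 2 cancer-core requirement; category percentages are
reported over the column's own total.

## Correlation injection in the generators

Gland- and region-level marker latents are drawn from a bivariate normal
whose *sample* correlation is made to equal the requested ρ exactly
(whiten the draw, recolour with the target covariance — the
`mvrnorm(empirical = TRUE)` construction; |ρ| = 1 and zero-spread cases
are constructed directly, and raw population-ρ draws are available with
`empirical=False`). Rationale: the generator's contract is that the
latent means *achieve* the requested correlation, which makes the
downstream pipeline estimate deviate from ρ only through pixel noise and
8-bit quantisation. With regions of ~10³ px and pixel noise sd 10, the
attenuation of a latent sd of 25 is below 10⁻³, so pipeline estimates sit
well inside the Fisher 95% interval of ρ; the acceptance run measures this
coverage over 100 seeds.

Cohort study conditions: 263 cancer regions at ρ = −0.35 and 239 KRT5+
regions at ρ = +0.14 (the compartment-specific association structure the
tissue analysis emulates); the benign-vs-cancer CAV1 effect is emulated as
a 71% higher cancer mean, exactly recovered through rendered zero-noise
cores. Clinical labels (Gleason group ≤6/7/≥8 at base frequencies
0.24/0.59/0.17, stage ≤pT2/pT3≤ at 0.58/0.42) are sampled through a
proportional-odds logistic link on the patient's latent CAV1 whose slope
defaults to zero, because the cohort analysis is a null result and the
null must be generable; under that null the cross-tab chi-square p-value
is uniform across seeds (KS-tested).

## Screen model and scoring

Per-cell intensities are log-normal (cell log-sd 0.35 per marker, well
log-sd 0.05). The regulatory hierarchy is wired in explicitly: an
ITGB1-targeting siRNA of efficiency e multiplies ITGB1 by (1−e) and CAV1
by (1−e)^c through the log-scale coupling slope c (default 0.66), while a
CAV1-targeting siRNA reduces CAV1 only. The same coupling acts on the
per-cell latent ITGB1 deviation, giving a control-well single-cell
CAV1–ITGB1 Pearson r of about 0.55 at the defaults — inside the 0.47–0.67
band the screen emulates. The default screen is 3 cell lines × 3 replicate
plates, 4 siRNAs per gene (efficiencies 0.70–0.85), 500 cells/well, 8
negative- and 4 positive-control wells per plate.

z-scores are control-based and classical by default (plate control-well
medians; sample sd with n−1), computed within each replicate plate and
averaged over the three replicates; a robust median/MAD variant is
available. The z′ factor uses the closed form on control-well medians.

A structural caveat, measured rather than hidden: because sample wells
fluctuate exactly like control wells, the null per-siRNA z has sd ≈ 1 *by
construction*, inflated further by estimating σ_ctrl from finitely many
control wells (t-like tails). At the default calling rule (≥ 2 of 4
siRNAs with mean-of-3 z > 1 in ≥ 1 of 3 lines) a panel of 20 null genes
therefore yields ~2.8 false regulator calls in expectation at 8 control
wells (~0.97 at 32; 0.57 only in the exact-σ idealisation). The hit
*hierarchy* is nevertheless recovered essentially deterministically: true
ITGB1 knockdowns shift the CAV1 read-out by ≫ 2σ_ctrl (z ≈ 11–17), so the
forward count is 4/4 in every line while the reverse direction stays at a
typical count of 0, far below the calling threshold. Screens that need a
tight null false-call rate should raise `min_sirnas`/`min_cell_lines` or
the z threshold; the defaults here reproduce the counting display, not an
error-controlled test.

## Expression workflow

Quantile normalisation floors raw values at 1, then maps each column's
order statistics to their across-sample mean; ties receive the mean of
their tied targets, so ranks are preserved, all sorted column vectors are
identical afterwards, and the map is idempotent. Probe-to-gene
summarisation is the one-step Tukey biweight with tuning constant c = 5
and ε = 10⁻⁴ on the MAD (the canonical microarray convention; one step,
no iteration). The three probe filters run in order — (1) keep genes
whose values lie within the per-sample [20th, 100th] percentile band in
every sample of at least one condition, (2) keep genes Present/Marginal
in every sample of at least one condition, (3) keep genes with CV > 1%
across all samples — with CV computed on the linear scale, since a 1% cut
on log2 values would remove almost nothing.

Differential expression uses logFC = class-mean difference on log2 (second
group minus first, e.g. mesenchymal − epithelial or treated − control) and
a moderated t: each gene's pooled variance is shrunk toward the across-gene
mean variance with prior weight df₀ = 4 and the statistic referred to a t
distribution with residual + prior df. This is an explicit empirical-Bayes
shrinkage with a *fixed* prior rather than a marginal-likelihood estimate
of df₀; when the generator's variances are exactly equal across genes the
fixed prior over-stabilises slightly and the test runs conservative
(measured type-I ≈ 0.038 at nominal 0.05 on a 5000-gene null, inside the
accepted [0.035, 0.065] window; sensitivity ≥ 0.99 at logFC 2, sd 0.25,
n = 4 vs 4). A plain Welch option exists. BH q-values come from the
standard step-up; selection is q < 0.05 ∧ |logFC| > 1.5 (strict).

Signatures are the k smallest-p genes per logFC sign (ties by |logFC|,
then gene id). Sub-clustering uses 1 − Pearson correlation with average
linkage, cut to n sub-clusters; among mesenchymal genes the sub-cluster
with the higher mean expression across epithelial samples is labelled
"transition". The generator's opt-in `transition_fraction` expresses that
block at half amplitude in half the epithelial panel — full-amplitude
bimodal expression would inflate within-class variance enough to push
transition genes out of any p-ranked signature, which is itself a property
the moderated test is expected to have. PCA class separation is standard
PCA on gene-standardised data, checked on the leading component; no
ANOVA-PCA/canonical-correspondence variant is attempted.

Anchor co-expression is plain Pearson r of each gene against the anchor
across samples, returning up to `top_n` genes with r > `r_min` (defaults
500 and 0.3), anchor first.

## Scale of the shipped simulations

Test and acceptance runs use sizes chosen to exercise the statistics at
meaningful power on one CPU: 100-seed coverage runs for the compartment
correlations (502 regions of 72² px per seed), 20-seed screen runs
(~0.45 M cells each), 100-seed 5000-gene null panels for DE calibration.
All generators are bit-deterministic in their seed.

## What the synthetic data does not model

No tissue texture, autofluorescence, optical PSF or staining chemistry;
glands are hard-edged ellipses, cells are non-overlapping disks. No
off-target siRNA effects, dose–response, or cell-cycle structure in the
screen. Expression matrices have homoscedastic Gaussian log2 noise and a
single co-expression factor per block — no batch structure, no
mean–variance trend. Passing tests therefore demonstrate correctness of
the estimators and procedures under their stated assumptions, not
robustness to the full messiness of real tissue or arrays. Clinical labels
carry no survival information, and the package makes no claims about the
biological identity of screen hits or signature genes.
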