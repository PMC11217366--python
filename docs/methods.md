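# Methods

## Classification models

**Nearest centroid.** A sample's profile over the classifier genes is
correlated with each subtype prototype; the call is the subtype with the
largest correlation. The research-style route uses Spearman rank
correlation (average ranks on ties), making calls invariant to any
strictly monotone per-sample transform; the clinical-style route uses
Pearson correlation on scaled expression and is invariant to positive
per-sample affine maps. Genes missing from the data are dropped pairwise
(correlation over the intersection) rather than imputed: rank or product-
moment correlation over the remaining genes is well defined, and
imputation would manufacture data. At least `min_genes` (default 3)
shared genes are required. Exact ties in the top correlation (within
1e-12) are flagged and broken by a configurable preference order
(default LumA, LumB, HER2-E, BL, NL); zero-variance profiles are an
error naming the sample. Each call retains the full correlation vector
and the top-two margin δ = ρ₍₁₎ − ρ₍₂₎; δ ≤ 0.1 marks a borderline
assignment, and the switching experiment reassigns such samples to the
runner-up centroid. "Within 0.1" is interpreted on the correlation
scale (equivalently, a 0.1 gap in 1 − ρ distance).

The Prosigna-style pipeline composes two scaling stages — housekeeping-
gene normalization (subtract the per-sample mean of the housekeeping
genes' log values; identical to dividing by their geometric mean on the
linear scale) and per-gene affine technical calibration — before
four-subtype Pearson classification, so it can never emit NL. The
proprietary scaling constants of the clinical assay are not public; both
stages take caller-supplied parameters.

**Gene-pair rules.** A rule (g_low, g_high) is true within a sample iff
expression(g_low) < expression(g_high); equality counts as false (a
deterministic convention matching strict "less than"). Classes are
scored by naive Bayes: log posterior_k = log prior_k + Σ_r [b_r log p_rk
+ (1 − b_r) log(1 − p_rk)], normalized by log-sum-exp. Conditional
probabilities must be additively smoothed into (0, 1) (training uses one
pseudo-count by default); priors default to uniform so a single-sample
("absolute") call does not encode cohort composition. The published
100-rule parameter set is not redistributed; the documented TSV format
loads any externally produced rule table, and `train_rules` fits a
rule set from labelled data (pairs drawn from the most variable genes,
ranked by mutual information between rule indicator and class label,
deterministic tie-breaking). `subset_rules` restricts a rule list to an
assay panel, mirroring the genome-wide-to-panel situation in which only
a fraction of rules remain evaluable.

## Normalization and centering

Count-derived transforms use log2(x + 1) so zeros stay finite (the
pseudo-count is a package choice; the plain "log2 counts per million"
description leaves zero counts undefined). Upper-quartile FPKM divides
each count by gene length (kb) times the sample's 75th percentile of
protein-coding counts, zeros included in the percentile. Quantile
normalization maps every sample onto the mean-of-order-statistics
distribution; within-sample ties receive the mean of the reference
values their ranks span (deterministic).

**Why subgroup-specific centering exists.** Centroid classifiers are
trained on per-gene-centered data from a *mixed* population. Centering a
trial cohort by its own per-gene median is correct only if the cohort
resembles that mixture; a cohort restricted to one receptor subgroup
(ER+/HER2−, hence luminal-dominant) has its median inside the luminal
bulk, so naive centering subtracts the luminal signature itself and
pushes every sample away from the luminal centroids. Two corrections
are implemented, both parameterized by a reference cohort with a flagged
subgroup:

* **sgPct** — per gene, find the percentile p_g of the *reference
  subgroup* at which the reference's *global* median sits, then subtract
  the trial cohort's own empirical quantile at p_g. Because p_g is a
  rank quantity it transfers across measurement platforms; the
  subtracted value is read off the trial's own scale. With the subgroup
  equal to the full cohort this reduces exactly to global-median
  centering. All quantile evaluations use linear interpolation between
  closest order statistics (numpy's default convention), applied
  identically when building and applying the reference, so centering the
  reference subgroup itself subtracts the reference global median to
  within interpolation round-off; percentiles are clamped to [0, 100]
  and clamped genes are flagged.
* **sgMd** — per gene, shift the trial so its median equals the
  reference subgroup median. The output sits on the reference's
  *absolute* scale, not the classifier's centered scale; in the
  cross-platform design it is therefore followed by technical
  calibration (TC), a per-gene affine map on the log scale fitted by
  least squares between paired measurements, which lands the data in the
  classifier's trained space. The package's scenario fits TC factors
  from the trial's platform onto the median-centered reference
  (classifier space), mirroring the sgMd.TC composition.

## Concordance statistics

Overall agreement is the diagonal fraction of the *unmerged* contingency
table over shared labels (labels one method cannot emit contribute no
diagonal). Cohen's κ = (P_o − P_e)/(1 − P_e) with P_e from marginal
products is computed after an optional label merge on both axes (NL into
LumA when comparing against a four-subtype assay); the large-sample
standard error √(P_o(1 − P_o)/(n(1 − P_e)²)) is reported but no bare
p-values. Conditional rates divide each cell by its column (or row)
total, with zero-total axes reported as undefined rather than erroring.
Clear-defined samples are those on which the two methods agree exactly
(no merging); the rest are discord. Reported roundings follow the
conventions of the source tables — integer percent for agreement and
conditional rates, one decimal for distributions, two decimals for κ,
always half-away-from-zero (68.75 → 69) — and raw fractions are always
retained alongside.

## Synthetic data: what it emulates and what it does not

`make_centroids` builds five prototypes whose pairwise correlations are
*exactly* ρ^d with ρ = 0.6 and d the distance on the line
NL–LumA–LumB–HER2-E–BL (a centered random gene basis is orthonormalized
by QR and mixed through the Cholesky factor of the target matrix), so
adjacent subtypes are genuinely confusable and the subtype continuum has
the right topology. Cohorts draw a true subtype from a composition
(reference default: LumA .45 / LumB .20 / HER2-E .10 / BL .20 / NL .05,
a mixed-population mix; trial default: LumA .55 / LumB .35 / HER2-E .08
/ BL .01 / NL .01, luminal-dominant as in an ER+/HER2− trial) and add
i.i.d. Gaussian noise per gene on the log scale. With centroid profiles
of unit SD, the default noise SD of 1.5 puts sample-to-own-centroid
correlations around 0.3–0.6 and leaves roughly one sample in eight
within 0.1 of its runner-up centroid — the borderline regime that
published margin scatters show; small noise values make every call
trivially clear-cut, which real cohorts are not. Platform distortion is
per-gene affine with log-normal scale (strictly positive by
construction, so no redraw branch is ever needed; log-SD 0.15, shift SD
0.5 by default) plus an optional per-sample random increasing
piecewise-linear map that exercises the rank-invariance claims. The
classifier centroids of a scenario are *trained* the standard way —
per-subtype mean profiles of the global-median-centered reference — not
copied from the generator.

The generator does **not** emulate: structured within-subtype biology
(samples interpolating between centroids; noise here is isotropic),
gene–gene correlation beyond the centroid structure, count-level
sampling noise, assay QC failures, or tumor-content effects. Passing
tests therefore demonstrate the *algorithms'* correctness and the
*directional* behaviour of the centering schemes under composition and
platform bias, not clinical performance on real tumors; the published
per-sample correlations and the exact switched fraction of the real
trial are functions of undeposited data and are deliberately not targets.

## Problem sizes and numerical choices

Scenario defaults (50 genes, 400 reference samples of which ~250 in the
subgroup, 222 trial samples) keep every per-gene quantile well estimated
while the full suite and the reproduction script each run in seconds.
The ten-seed centering experiment and the three-point bias grid (log-SD
0.05/0.3/0.9, three seeds per point, κ averaged) are sized so the
reported orderings are stable across seeds. Seed handling derives all
sub-seeds from a single `SeedSequence`, making every artifact a
deterministic function of (config, seed). Degenerate inputs error
loudly and early: zero library sizes, zero upper-quartile counts,
zero-variance profiles, subgroups smaller than two, empty gene
intersections, unsmoothed probabilities, degenerate κ marginals.

## Known limitations

* The sgPct percentile inversion assumes the reference global median
  lies within the subgroup's observed range; genes outside it are
  clamped and flagged, and the self-consistency guarantee excludes them.
* κ's standard error is the simple large-sample form, adequate for the
  cohort sizes here but not exact in small tables.
* `train_rules` is a deliberately simple mutual-information ranker — a
  stand-in training procedure for testing the rule machinery, not a
  re-derivation of any published rule list.
* The linear adjacency audit covers the four tumor subtypes only;
  switches involving NL are reported as an error by design, since NL has
  no position on the published ordering.
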