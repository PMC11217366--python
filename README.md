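# bcsubtype

Tools for comparing intrinsic breast-cancer molecular subtyping methods on
the same samples.

Breast tumors are routinely classified into five intrinsic subtypes —
luminal A (LumA), luminal B (LumB), HER2-enriched (HER2-E), basal-like (BL)
and normal-like (NL) — by comparing a tumor's expression profile over a
classifier gene set against prototype profiles (centroids). Different
implementations of this idea (rank-correlation nearest centroid on
research data, Pearson-correlation on a scaled clinical assay,
single-sample gene-pair rules with a naive-Bayes decision) can disagree
substantially on identical samples, and the disagreement depends heavily
on how the expression data were normalized and centered, especially when
the cohort contains only one receptor-defined subgroup (e.g. ER+/HER2−).
This package implements the classifiers, the normalization/centering
schemes, the agreement statistics used to quantify such disagreements, and
a ground-truthed synthetic-data generator so the full comparison design can
be exercised end to end without access to restricted trial data.

## What is implemented

* **Nearest-centroid classification** — for sample profile *x* and centroid
  *c_k*, compute ρ_k = corr(x, c_k) (Spearman or Pearson) over the shared
  genes and call argmax_k ρ_k; every call carries its full correlation
  vector, the top-two margin δ = ρ₍₁₎ − ρ₍₂₎, and tie/switch flags.
  A Prosigna-style route chains housekeeping normalization and per-gene
  affine calibration before four-subtype Pearson classification.
* **Gene-pair rule classification** — rules "expression(g_low) <
  expression(g_high)" evaluated within each sample, combined by naive
  Bayes with smoothed per-class conditional probabilities; invariant to
  any strictly monotone per-sample transform. Includes panel subsetting
  and a rule-training helper.
* **Normalization and centering** — log2 CPM, quantile normalization,
  upper-quartile FPKM, housekeeping normalization; subgroup-specific
  percentile centering (sgPct), subgroup-specific median centering (sgMd)
  and per-gene affine technical calibration (TC) for cohorts drawn from a
  single receptor subgroup and/or profiled on a different platform than
  the classifier's training data.
* **Concordance statistics** — contingency tables, overall agreement,
  Cohen's κ = (P_o − P_e)/(1 − P_e) with label merging (e.g. NL→LumA),
  row/column-conditional misassignment rates, subtype distributions, and
  the clear-defined vs discord sample partition.
* **Synthetic scenario** — correlated subtype centroids on the
  LumA–LumB–HER2-E–BL similarity line, a mixed reference cohort with a
  luminal ER+-like subgroup, a luminal-dominant trial cohort, platform
  distortions, and Gaussian noise; fully deterministic under a seed.

The published cross-tabulations of two trial comparisons (n = 222 and
n = 224) ship as plain-text fixtures (`bcsubtype.datasets`), so all
table-derived statistics are recomputed, never hard-coded.

## Worked example

```python
import bcsubtype as bc
from bcsubtype.datasets import load_paloma2_table1
from bcsubtype.concordance import calls_from_contingency

table = load_paloma2_table1()          # 5x4 cross-tabulation, n = 222
frac, pct = bc.overall_agreement(table)
kappa, se = bc.cohens_kappa(table, {"NL": "LumA"})
rates = bc.conditional_rates(table)    # column-conditional percentages
print(f"agreement {pct}% ({frac:.3f}), kappa {bc.round_half_away(kappa, 2)}")
print(f"centroid-LumB called LumA by rules: {rates['percent'].loc['LumA', 'LumB']}%")
```

prints

```
agreement 54% (0.536), kappa 0.3
centroid-LumB called LumA by rules: 46%
```

i.e. the two methods agree on barely half the samples (119/222
clear-defined); chance-corrected agreement is only fair (κ = 0.30 after
merging NL into LumA), and nearly half of the clinical assay's LumB
calls are demoted to LumA by the rule-based classifier.

The numbered scripts under `analysis/` run the full study: published-table
concordance (`01`), synthetic scenario generation (`02`), the centering
comparison showing that naive within-cohort median centering of a
luminal-dominant trial costs ~17 accuracy points that subgroup-percentile
centering recovers (`03`), and the borderline-margin / second-centroid
switching experiment (`04`). Each writes its tables under `results/`.

A `bcsubtype` command-line interface wraps the same functions
(`classify`, `classify-rules`, `switch`, `compare`, `simulate`, `run`).

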