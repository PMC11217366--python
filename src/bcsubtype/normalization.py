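"""Expression pre-processing ahead of centroid classification.

Covers within-platform normalization (log2 counts-per-million, quantile
normalization, upper-quartile FPKM, housekeeping-gene normalization) and
the cohort/platform alignment schemes used before nearest-centroid
subtyping of receptor-defined trial cohorts:

* subgroup-specific percentile centering (sgPct) — per gene, find the
  percentile of a reference subgroup (e.g. the ER+/HER2- slice of a
  mixed reference cohort) at which the reference's *global* median sits,
  then center the test cohort by subtracting its own empirical quantile
  at that percentile.  Being rank-based, the percentile transfers across
  platforms.
* subgroup-specific median centering (sgMd) — per gene, shift the test
  cohort so its median lands on the reference subgroup median.
* technical calibration (TC) — per-gene affine map (on the log scale)
  from one platform's measurement scale onto another's, applied after
  sgMd when the classifier was trained on a different platform.

Quantile conventions: all percentile/quantile evaluations use linear
interpolation between closest order statistics (numpy's default), applied
identically when building and applying sgPct so that centering the
reference subgroup itself recovers the reference global median.
Log transforms of count-derived quantities use ``log2(x + 1)`` so zero
counts stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import AlignmentError, ExpressionMatrix, FormatError


class NormalizationError(ValueError):
    """A normalization step received unusable input."""


# ---------------------------------------------------------------------------
# within-platform normalization


def log2_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Transform raw counts into log2 counts per million (plus one).

    Per sample, ``cpm = counts / library_size * 1e6``; the output is
    ``log2(cpm + 1)``.  Pre-log CPM columns sum to 1e6 by construction.
    """
    if counts.scale != "counts":
        raise NormalizationError(f"expected scale='counts', got {counts.scale!r}")
    v = counts.values
    libsize = v.sum(axis=0)
    zero = np.flatnonzero(libsize <= 0)
    if zero.size:
        bad = [counts.sample_ids[i] for i in zero]
        raise NormalizationError(f"zero library size for sample(s): {', '.join(bad)}")
    cpm = v / libsize * 1e6
    return counts.with_values(np.log2(cpm + 1.0), scale="log2cpm")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean-of-order-statistics distribution.

    After normalization each sample's sorted value vector equals the
    across-sample mean of sorted vectors; values tied within a sample
    receive the mean of the reference values their ranks span.
    """
    if matrix.n_samples < 2:
        raise NormalizationError("quantile normalization needs at least 2 samples")
    v = matrix.values
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = v[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties: average the reference values spanned by each tied group
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(col)]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        out[:, j] = assigned
    return matrix.with_values(out)


def uq_fpkm(
    counts: ExpressionMatrix,
    gene_length_bp: pd.Series,
    protein_coding: pd.Series,
) -> ExpressionMatrix:
    """Upper-quartile FPKM on the log2 scale.

    Per sample, each count is divided by gene length (kb) times the 75th
    percentile of that sample's protein-coding gene counts; the output is
    ``log2(value + 1)``.  Zero-count protein-coding genes participate in
    the percentile.
    """
    if counts.scale != "counts":
        raise NormalizationError(f"expected scale='counts', got {counts.scale!r}")
    lengths = gene_length_bp.reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise NormalizationError(f"missing gene length for: {missing}")
    if (lengths <= 0).any():
        raise NormalizationError("gene lengths must be positive")
    coding = protein_coding.reindex(counts.gene_ids).fillna(False).astype(bool)
    if not coding.any():
        raise NormalizationError("no protein-coding genes available for the upper quartile")
    v = counts.values
    uq = np.percentile(v[coding.to_numpy()], 75, axis=0)
    zero = np.flatnonzero(uq <= 0)
    if zero.size:
        bad = [counts.sample_ids[i] for i in zero]
        raise NormalizationError(f"zero upper-quartile count for sample(s): {', '.join(bad)}")
    fpkm = v / (lengths.to_numpy()[:, None] / 1e3 * uq[None, :])
    return counts.with_values(np.log2(fpkm + 1.0), scale="logfpkm")


def housekeeping_normalize(matrix: ExpressionMatrix, hk_genes) -> ExpressionMatrix:
    """Subtract each sample's mean log expression over housekeeping genes.

    On the log scale this equals dividing by the geometric mean of the
    housekeeping genes on the linear scale.
    """
    if matrix.scale == "counts":
        raise NormalizationError("housekeeping normalization expects log-scale input")
    hk = list(hk_genes)
    missing = [g for g in hk if g not in matrix.data.index]
    if missing:
        raise NormalizationError(f"housekeeping gene(s) absent: {', '.join(missing)}")
    offsets = matrix.data.loc[hk].to_numpy().mean(axis=0)
    return matrix.with_values(matrix.values - offsets[None, :])


# ---------------------------------------------------------------------------
# subgroup-specific centering


@dataclass
class NormalizationReference:
    """Per-gene centering parameters derived from a mixed reference cohort.

    ``mapped_percentile[g]`` is the percentile of the reference
    *subgroup* at which the reference *global* median of gene ``g`` sits
    (clamped to [0, 100]; ``clamped`` flags genes whose global median
    falls outside the subgroup's observed range).
    """

    gene_ids: list
    global_median: np.ndarray
    subgroup_median: np.ndarray
    mapped_percentile: np.ndarray
    clamped: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.mapped_percentile, dtype=float)
        if ((p < 0) | (p > 100)).any():
            raise FormatError("mapped percentiles must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "global_median": self.global_median,
                "subgroup_median": self.subgroup_median,
                "mapped_percentile": self.mapped_percentile,
                "clamped": self.clamped.astype(int),
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def write_reference(ref: NormalizationReference, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if ref.source:
            fh.write(f"# source: {ref.source}\n")
        ref.to_frame().to_csv(fh, sep="\t", index_label="gene_id")


def read_reference(path) -> NormalizationReference:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return NormalizationReference(
        gene_ids=[str(g) for g in df.index],
        global_median=df["global_median"].to_numpy(float),
        subgroup_median=df["subgroup_median"].to_numpy(float),
        mapped_percentile=df["mapped_percentile"].to_numpy(float),
        clamped=df["clamped"].to_numpy() != 0,
    )


def build_sgpct_reference(
    reference: ExpressionMatrix, subgroup: np.ndarray, source: str = ""
) -> NormalizationReference:
    """Locate each gene's reference global median within the subgroup.

    ``subgroup`` is a boolean mask over the reference samples (e.g. the
    ER+/HER2--like slice).  For every gene the subgroup's empirical
    quantile function (linear interpolation between order statistics) is
    inverted at the full-cohort median; the resulting percentile is
    clamped to [0, 100].  Construction verifies that evaluating the
    subgroup quantile at the stored percentile reproduces the global
    median (up to interpolation tolerance) for every non-clamped gene.
    """
    mask = np.asarray(subgroup, dtype=bool)
    if mask.shape != (reference.n_samples,):
        raise NormalizationError("subgroup mask length must match the sample count")
    if mask.sum() < 2:
        raise NormalizationError("subgroup must contain at least 2 samples")
    v = reference.values
    global_median = np.median(v, axis=1)
    sub = np.sort(v[:, mask], axis=1)
    m = sub.shape[1]
    grid = np.linspace(0.0, 100.0, m)
    pct = np.empty(reference.n_genes)
    for g in range(reference.n_genes):
        pct[g] = np.interp(global_median[g], sub[g], grid)
    clamped = (global_median < sub[:, 0]) | (global_median > sub[:, -1])
    # self-consistency of the inversion (non-clamped genes only)
    check = np.array(
        [np.percentile(sub[g], pct[g]) for g in range(reference.n_genes)]
    )
    ok = clamped | (np.abs(check - global_median) <= 1e-8 * np.maximum(1, np.abs(global_median)))
    if not ok.all():
        bad = [reference.gene_ids[i] for i in np.flatnonzero(~ok)]
        raise NormalizationError(f"percentile inversion failed for gene(s): {bad}")
    return NormalizationReference(
        gene_ids=reference.gene_ids,
        global_median=global_median,
        subgroup_median=np.median(v[:, mask], axis=1),
        mapped_percentile=pct,
        clamped=clamped,
        source=source,
    )


def _require_aligned(test: ExpressionMatrix, ref: NormalizationReference) -> None:
    missing = [g for g in test.gene_ids if g not in set(ref.gene_ids)]
    if missing:
        raise AlignmentError(f"gene(s) absent from normalization reference: {missing}")


def sgpct_center(test: ExpressionMatrix, ref: NormalizationReference) -> ExpressionMatrix:
    """Center each gene at the test cohort's quantile at the mapped percentile.

    With all percentiles at 50 this reduces to per-gene median centering
    of the test cohort; with the subgroup-derived percentiles it centers
    a composition-biased cohort at an estimate of the *reference global
    median*, expressed through the cohort's own measurement scale.
    """
    _require_aligned(test, ref)
    pos = {g: i for i, g in enumerate(ref.gene_ids)}
    idx = np.array([pos[g] for g in test.gene_ids])
    p = np.asarray(ref.mapped_percentile, float)[idx]
    v = test.values
    centers = np.array([np.percentile(v[g], p[g]) for g in range(test.n_genes)])
    return test.with_values(v - centers[:, None], scale="centered")


def sgmd_center(test: ExpressionMatrix, ref: NormalizationReference) -> ExpressionMatrix:
    """Shift each gene so the test cohort median equals the reference subgroup median."""
    _require_aligned(test, ref)
    pos = {g: i for i, g in enumerate(ref.gene_ids)}
    idx = np.array([pos[g] for g in test.gene_ids])
    target = np.asarray(ref.subgroup_median, float)[idx]
    v = test.values
    shift = np.median(v, axis=1) - target
    return test.with_values(v - shift[:, None], scale="centered")


# ---------------------------------------------------------------------------
# technical calibration


@dataclass
class CalibrationFactors:
    """Per-gene affine map on the log scale: ``out = scale * x + shift``."""

    gene_ids: list
    scale: np.ndarray
    shift: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scale, dtype=float)
        if not np.isfinite(s).all() or not np.isfinite(np.asarray(self.shift, float)).all():
            raise FormatError("calibration factors must be finite")
        if (s <= 0).any():
            raise FormatError("calibration scale factors must be positive")

    def inverse(self) -> "CalibrationFactors":
        s = np.asarray(self.scale, float)
        b = np.asarray(self.shift, float)
        return CalibrationFactors(list(self.gene_ids), 1.0 / s, -b / s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scale": self.scale, "shift": self.shift},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def write_calibration(factors: CalibrationFactors, path) -> None:
    factors.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_calibration(path) -> CalibrationFactors:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return CalibrationFactors(
        [str(g) for g in df.index],
        df["scale"].to_numpy(float),
        df["shift"].to_numpy(float),
    )


def apply_technical_calibration(
    matrix: ExpressionMatrix, factors: CalibrationFactors
) -> ExpressionMatrix:
    """Apply the per-gene affine platform correction (log scale)."""
    pos = {g: i for i, g in enumerate(factors.gene_ids)}
    missing = [g for g in matrix.gene_ids if g not in pos]
    if missing:
        raise AlignmentError(f"no calibration factor for gene(s): {missing}")
    idx = np.array([pos[g] for g in matrix.gene_ids])
    s = np.asarray(factors.scale, float)[idx][:, None]
    b = np.asarray(factors.shift, float)[idx][:, None]
    return matrix.with_values(s * matrix.values + b)


def fit_calibration_factors(
    source: ExpressionMatrix, target: ExpressionMatrix
) -> CalibrationFactors:
    """Per-gene least-squares fit of ``target ~ scale * source + shift``.

    ``source`` and ``target`` must share genes and samples (paired
    measurements of the same material on two platforms).  The fitted
    factors, applied to ``source``, map it onto the target's scale.
    """
    if source.gene_ids != target.gene_ids or source.sample_ids != target.sample_ids:
        raise AlignmentError("calibration fitting needs identically indexed paired matrices")
    x = source.values
    y = target.values
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    if (sxx <= 0).any():
        bad = [source.gene_ids[i] for i in np.flatnonzero(sxx <= 0)]
        raise NormalizationError(f"zero variance in source for gene(s): {bad}")
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    slope = sxy / sxx
    intercept = ym[:, 0] - slope * xm[:, 0]
    return CalibrationFactors(list(source.gene_ids), slope, intercept)


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Naive within-cohort per-gene median centering (no external reference)."""
    v = matrix.values
    return matrix.with_values(v - np.median(v, axis=1, keepdims=True), scale="centered")
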