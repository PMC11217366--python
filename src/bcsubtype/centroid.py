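"""Nearest-centroid intrinsic subtype classification.

A sample is assigned to the subtype whose prototype profile (centroid)
it correlates with most strongly across the classifier genes — Spearman
rank correlation for the research PAM50-style route, Pearson correlation
on scaled expression for the Prosigna-style route.  Besides the call,
every sample carries its full correlation vector, the top-two margin
(largest minus second-largest correlation), and tie/switch flags, which
feed the borderline-subtype analyses: small margins mark samples sitting
near the boundary between two subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import (
    AlignmentError,
    CentroidSet,
    ExpressionMatrix,
    SubtypeCallTable,
    align_genes,
    canonical_label_order,
)
from .normalization import (
    CalibrationFactors,
    apply_technical_calibration,
    housekeeping_normalize,
)

#: linear ordering of the non-normal subtypes used in the adjacency audit
ADJACENT_ORDER = ("LumA", "LumB", "HER2-E", "BL")

_TIE_TOL = 1e-12


class ClassificationError(ValueError):
    """The classifier cannot produce a well-defined call."""


@dataclass
class ClassifierConfig:
    method: str = "spearman"
    min_genes: int = 3
    tie_order: list[str] | None = None
    switch_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "pearson"):
            raise ClassificationError(f"unknown method {self.method!r}")
        if self.min_genes < 3:
            raise ClassificationError("min_genes must be at least 3")
        if self.switch_threshold < 0:
            raise ClassificationError("switch threshold must be non-negative")


def _correlations(x: np.ndarray, c: np.ndarray, method: str, sample_ids) -> np.ndarray:
    """Column-wise correlations: x (genes x S) against c (genes x K)."""
    if method == "spearman":
        x = rankdata(x, axis=0)
        c = rankdata(c, axis=0)
    xc = x - x.mean(axis=0)
    cc = c - c.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    cn = np.linalg.norm(cc, axis=0)
    flat = np.flatnonzero(xn == 0)
    if flat.size:
        bad = [sample_ids[i] for i in flat]
        raise ClassificationError(
            f"zero-variance profile for sample(s): {', '.join(map(str, bad))}"
        )
    if (cn == 0).any():
        raise ClassificationError("zero-variance centroid profile")
    rho = (xc.T @ cc) / np.outer(xn, cn)
    return np.clip(rho, -1.0, 1.0)


def _resolve_calls(rho: np.ndarray, labels: list[str], tie_order: list[str]):
    order_pos = {l: i for i, l in enumerate(tie_order)}
    pos = np.array([order_pos.get(l, len(tie_order)) for l in labels])
    best = rho.max(axis=1)
    second = np.partition(rho, -2, axis=1)[:, -2] if rho.shape[1] >= 2 else best
    margin = best - second
    calls, ties = [], []
    labels_arr = np.asarray(labels)
    for i in range(rho.shape[0]):
        near = np.flatnonzero(rho[i] >= best[i] - _TIE_TOL)
        ties.append(len(near) > 1)
        calls.append(labels_arr[near[np.argmin(pos[near])]])
    return np.asarray(calls), margin, np.asarray(ties)


def classify(
    matrix: ExpressionMatrix,
    centroids: CentroidSet,
    config: ClassifierConfig | None = None,
) -> SubtypeCallTable:
    """Assign each sample to the nearest centroid by correlation.

    Correlations are computed over the genes shared between the matrix
    and the centroid table (missing classifier genes are dropped
    pairwise); at least ``config.min_genes`` shared genes are required.
    Exact ties (within 1e-12) are flagged and broken by ``tie_order``.
    """
    config = config or ClassifierConfig(method=centroids.method)
    aligned, report = align_genes(matrix, centroids.gene_ids)
    if report.n_retained < config.min_genes:
        raise AlignmentError(
            f"only {report.n_retained} genes overlap the centroid set; "
            f"need at least {config.min_genes}"
        )
    cvals = centroids.data.loc[aligned.gene_ids].to_numpy(dtype=float)
    rho = _correlations(aligned.values, cvals, config.method, aligned.sample_ids)
    labels = centroids.subtype_labels
    tie_order = config.tie_order or canonical_label_order(labels)
    calls, margin, ties = _resolve_calls(rho, labels, tie_order)
    table = pd.DataFrame(
        {"call": calls}, index=pd.Index(aligned.sample_ids, name="sample_id")
    )
    for k, lab in enumerate(labels):
        table[f"rho_{lab}"] = rho[:, k]
    table["margin"] = margin
    table["tie"] = ties
    table["switched"] = False
    return SubtypeCallTable(table, labels)


def prosigna_style_classify(
    matrix: ExpressionMatrix,
    centroids: CentroidSet,
    hk_genes,
    factors: CalibrationFactors,
    config: ClassifierConfig | None = None,
) -> SubtypeCallTable:
    """Clinical-assay-style pipeline: scale, then Pearson nearest centroid.

    Two scaling stages precede classification: housekeeping-gene
    normalization and a per-gene affine calibration onto the centroid
    training scale.  The centroid set must carry exactly the four
    non-normal subtypes, so an NL call can never be emitted.
    """
    if "NL" in centroids.subtype_labels or len(centroids.subtype_labels) != 4:
        raise ClassificationError(
            "Prosigna-style classification requires the 4 non-normal subtype centroids"
        )
    config = config or ClassifierConfig(method="pearson")
    if config.method != "pearson":
        raise ClassificationError("Prosigna-style classification uses Pearson correlation")
    scaled = housekeeping_normalize(matrix, hk_genes)
    calibrated = apply_technical_calibration(scaled, factors)
    return classify(calibrated, centroids, config)


# ---------------------------------------------------------------------------
# top-two margins and the switching experiment


def top_two(calls: SubtypeCallTable) -> pd.DataFrame:
    """Largest and second-largest correlations with their subtype labels.

    Returns a frame with columns ``best_label, second_label, rho_best,
    rho_second, delta`` (delta = rho_best - rho_second >= 0), the raw
    material of margin scatter plots and the switching experiment.
    """
    if len(calls.subtypes) < 2:
        raise ClassificationError("top_two needs at least two centroids")
    rho = calls.correlations.to_numpy()
    labels = np.asarray(calls.subtypes)
    order_pos = {l: i for i, l in enumerate(canonical_label_order(calls.subtypes))}
    pos = np.array([order_pos[l] for l in labels])
    rows = []
    for i in range(rho.shape[0]):
        # sort by descending rho, canonical order breaking exact ties
        idx = sorted(range(len(labels)), key=lambda k: (-rho[i, k], pos[k]))
        b, s = idx[0], idx[1]
        rows.append(
            (labels[b], labels[s], rho[i, b], rho[i, s], rho[i, b] - rho[i, s])
        )
    return pd.DataFrame(
        rows,
        columns=["best_label", "second_label", "rho_best", "rho_second", "delta"],
        index=calls.table.index,
    )


@dataclass
class SwitchSummary:
    n_switched: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_switched / self.n_total if self.n_total else 0.0


def switch_to_second(
    calls: SubtypeCallTable, threshold: float = 0.1
) -> tuple[SubtypeCallTable, SwitchSummary]:
    """Move borderline samples to their second-closest centroid.

    Samples whose top-two correlation gap is at most ``threshold`` have
    their call replaced by the second-best label and are flagged
    ``switched``; everything else is untouched.
    """
    if threshold < 0:
        raise ClassificationError("switch threshold must be non-negative")
    tt = top_two(calls)
    table = calls.table.copy()
    hit = tt["delta"].to_numpy() <= threshold
    table.loc[hit, "call"] = tt.loc[hit, "second_label"]
    table["switched"] = hit
    switched = SubtypeCallTable(table, calls.subtypes)
    return switched, SwitchSummary(int(hit.sum()), len(table))


def adjacency_audit(
    original: SubtypeCallTable,
    switched: SubtypeCallTable,
    order=ADJACENT_ORDER,
) -> tuple[pd.DataFrame, dict]:
    """Label each switch transition adjacent/non-adjacent on a linear subtype order.

    Two subtypes are adjacent when they are neighbours in ``order``
    (default LumA-LumB-HER2-E-BL).  Raises on labels outside the order.
    """
    if original.sample_ids != switched.sample_ids:
        raise ClassificationError("call tables cover different samples")
    pos = {l: i for i, l in enumerate(order)}
    rows = []
    for sid, before, after, flag in zip(
        original.sample_ids,
        original.calls,
        switched.calls,
        switched.table["switched"],
    ):
        if not flag:
            continue
        if before not in pos or after not in pos:
            raise ClassificationError(
                f"label outside adjacency order {list(order)}: {before!r} -> {after!r}"
            )
        rows.append((sid, before, after, abs(pos[before] - pos[after]) == 1))
    audit = pd.DataFrame(rows, columns=["sample_id", "from", "to", "adjacent"])
    summary = {
        "n_switched": len(audit),
        "n_adjacent": int(audit["adjacent"].sum()) if len(audit) else 0,
        "n_non_adjacent": int((~audit["adjacent"]).sum()) if len(audit) else 0,
    }
    return audit, summary
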