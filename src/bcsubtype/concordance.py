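"""Cross-method agreement statistics for subtype call tables.

Two classification methods applied to the same cohort are compared via
their contingency table: overall agreement (diagonal fraction), Cohen's
chance-corrected kappa (optionally after merging labels one method does
not emit, e.g. NL into LumA for a four-subtype clinical assay),
row/column-conditional misassignment rates, per-method subtype
distributions, and the partition into clear-defined samples (methods
agree) versus discord samples (methods disagree).

Reporting conventions: agreements and conditional rates are rounded to
integer percent, distributions to one decimal, kappa to two decimals —
all half-away-from-zero — and the raw fractions are always retained
alongside the rounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import SubtypeCallTable, canonical_label_order


class ConcordanceError(ValueError):
    """Concordance statistics received unusable input."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the reporting convention here)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _labels_of(calls) -> pd.Series:
    if isinstance(calls, SubtypeCallTable):
        return calls.calls
    return pd.Series(calls)


# ---------------------------------------------------------------------------
# contingency tables


@dataclass
class ContingencyTable:
    """Cross-classification counts; rows = method A, columns = method B."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ConcordanceError("contingency counts must be non-negative integers")
        self.counts = self.counts.astype(int)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def labels_a(self) -> list[str]:
        return list(self.counts.index)

    @property
    def labels_b(self) -> list[str]:
        return list(self.counts.columns)

    def merged(self, merge_map: dict | None) -> "ContingencyTable":
        """Collapse labels on both axes according to ``merge_map`` (e.g. NL->LumA)."""
        if not merge_map:
            return self
        df = self.counts.copy()
        df = df.rename(index=merge_map, columns=merge_map)
        df = df.groupby(level=0).sum().T.groupby(level=0).sum().T
        order_r = canonical_label_order(df.index)
        order_c = canonical_label_order(df.columns)
        return ContingencyTable(df.loc[order_r, order_c])


def contingency(calls_a, calls_b) -> ContingencyTable:
    """Cross-tabulate two call tables over the same samples."""
    a = _labels_of(calls_a)
    b = _labels_of(calls_b)
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index) ^ set(b.index))
        raise ConcordanceError(f"sample sets differ: {diff}")
    b = b.reindex(a.index)
    rows = canonical_label_order(a.unique())
    cols = canonical_label_order(b.unique())
    table = pd.crosstab(a, b).reindex(index=rows, columns=cols, fill_value=0)
    table.index.name = "method_a"
    table.columns.name = "method_b"
    return ContingencyTable(table)


def overall_agreement(table: ContingencyTable) -> tuple[float, int]:
    """Diagonal fraction over shared labels; also as integer percent.

    Computed on the *unmerged* table: labels present on only one axis
    (e.g. NL for a four-subtype assay) contribute no diagonal cell.
    """
    shared = [l for l in table.labels_a if l in table.labels_b]
    if not shared:
        raise ConcordanceError("no shared labels between the two methods")
    diag = sum(int(table.counts.loc[l, l]) for l in shared)
    frac = diag / table.n
    return frac, int(round_half_away(100 * frac))


def cohens_kappa(
    table: ContingencyTable, merge_map: dict | None = None
) -> tuple[float, float]:
    """Unweighted Cohen's kappa (and its large-sample standard error).

    ``merge_map`` is applied to both axes first; after merging, rows and
    columns must share a label set.  kappa = (P_o - P_e) / (1 - P_e)
    with P_e from the marginal products.
    """
    m = table.merged(merge_map)
    labels = [l for l in m.labels_a if l in m.labels_b]
    if set(m.labels_a) != set(m.labels_b):
        extra = sorted(set(m.labels_a) ^ set(m.labels_b))
        raise ConcordanceError(
            f"labels not shared after merging: {extra}; extend the merge map"
        )
    c = m.counts.loc[labels, labels].to_numpy(dtype=float)
    n = c.sum()
    po = np.trace(c) / n
    pe = float((c.sum(axis=1) / n) @ (c.sum(axis=0) / n))
    if 1 - pe <= 1e-12:
        raise ConcordanceError("degenerate marginals: chance agreement is 1, kappa undefined")
    kappa = (po - pe) / (1 - pe)
    se = float(np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2)))
    return float(kappa), se


def conditional_rates(table: ContingencyTable, axis: str = "columns") -> dict:
    """Per-cell percentages of each column (or row) total.

    ``axis='columns'`` answers "of the samples method B assigned label x,
    what share did method A put in label y" — the misassignment rates
    quoted in cross-method comparisons.  Zero-total axes are reported as
    undefined (None), never as an error.
    """
    if axis not in ("columns", "rows"):
        raise ConcordanceError("axis must be 'columns' or 'rows'")
    c = table.counts.to_numpy(dtype=float)
    if axis == "columns":
        totals = c.sum(axis=0)[None, :]
    else:
        totals = c.sum(axis=1)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(totals > 0, c / np.where(totals == 0, 1, totals), np.nan)
    frac = pd.DataFrame(vals, index=table.labels_a, columns=table.labels_b)
    percent = frac.map(
        lambda f: None if pd.isna(f) else int(round_half_away(100 * f))
    )
    return {"fraction": frac, "percent": percent, "axis": axis}


def partition_discord(calls_a, calls_b) -> tuple[list[str], list[str]]:
    """Split samples into clear-defined (exact agreement) and discord ids."""
    a = _labels_of(calls_a)
    b = _labels_of(calls_b)
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index) ^ set(b.index))
        raise ConcordanceError(f"sample sets differ: {diff}")
    b = b.reindex(a.index)
    agree = a == b
    return list(a.index[agree]), list(a.index[~agree])


def distribution(calls) -> pd.DataFrame:
    """Per-subtype counts and one-decimal percentages for one method."""
    labels = _labels_of(calls)
    if len(labels) == 0:
        raise ConcordanceError("empty call set")
    counts = labels.value_counts()
    order = canonical_label_order(counts.index)
    counts = counts.reindex(order)
    out = pd.DataFrame({"count": counts.astype(int)})
    out["percent"] = [round_half_away(100 * c / len(labels), 1) for c in counts]
    out.index.name = "subtype"
    return out


# ---------------------------------------------------------------------------
# fixture helpers and full reports


def calls_from_contingency(
    table: ContingencyTable, prefix: str = "S"
) -> tuple[pd.Series, pd.Series]:
    """Expand a contingency table into two per-sample label vectors.

    Synthetic deterministic sample ids; useful for recomputing
    sample-level statistics from published cross-tabulations.
    """
    ids, la, lb = [], [], []
    i = 0
    for ra in table.labels_a:
        for cb in table.labels_b:
            for _ in range(int(table.counts.loc[ra, cb])):
                i += 1
                ids.append(f"{prefix}{i:04d}")
                la.append(ra)
                lb.append(cb)
    idx = pd.Index(ids, name="sample_id")
    return pd.Series(la, index=idx, name="method_a"), pd.Series(lb, index=idx, name="method_b")


def concordance_report(
    calls_a,
    calls_b,
    merge_map: dict | None = None,
    name_a: str = "method_a",
    name_b: str = "method_b",
) -> dict:
    """Full cross-method comparison as a JSON-serializable dictionary."""
    table = contingency(calls_a, calls_b)
    frac, pct = overall_agreement(table)
    kappa, se = cohens_kappa(table, merge_map)
    clear, discord = partition_discord(calls_a, calls_b)
    rates = conditional_rates(table, axis="columns")
    dist_a = distribution(calls_a)
    dist_b = distribution(calls_b)
    return {
        "n": table.n,
        "methods": [name_a, name_b],
        "contingency": {
            "labels_a": table.labels_a,
            "labels_b": table.labels_b,
            "counts": table.counts.to_numpy().tolist(),
        },
        "agreement": {"fraction": frac, "percent": pct},
        "kappa": {
            "value": kappa,
            "rounded": round_half_away(kappa, 2),
            "se": se,
            "merge_map": merge_map or {},
        },
        "conditional_rates": {
            "axis": "columns",
            "percent": [
                [None if v is None else int(v) for v in row]
                for row in rates["percent"].to_numpy().tolist()
            ],
            "fraction": [
                [None if pd.isna(v) else float(v) for v in row]
                for row in rates["fraction"].to_numpy().tolist()
            ],
        },
        "distributions": {
            name_a: {
                s: {"count": int(r["count"]), "percent": float(r["percent"])}
                for s, r in dist_a.iterrows()
            },
            name_b: {
                s: {"count": int(r["count"]), "percent": float(r["percent"])}
                for s, r in dist_b.iterrows()
            },
        },
        "clear_defined_ids": clear,
        "discord_ids": discord,
        "n_clear_defined": len(clear),
        "n_discord": len(discord),
    }
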