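"""Tabular containers and file formats for subtyping pipelines.

All on-disk formats are plain text: tab-separated tables (UTF-8, ``.``
decimal separator) for matrices, centroids, rules and per-sample calls,
and JSON for concordance reports.  Expression tables are oriented
genes-in-rows, samples-in-columns, with the first header cell literally
``gene_id``; a transpose flag is available for column-major exports.

The subtype label vocabulary is fixed and case-sensitive:
LumA, LumB, HER2-E, BL, NL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical subtype ordering used for tables, tie-breaking and reports
SUBTYPE_ORDER = ["LumA", "LumB", "HER2-E", "BL", "NL"]

#: admissible scale tags for an ExpressionMatrix
SCALES = ("counts", "log2cpm", "logfpkm", "log_generic", "centered")


class FormatError(ValueError):
    """A file or in-memory table violates the documented format."""


class AlignmentError(ValueError):
    """Gene/sample universes of two objects cannot be reconciled."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise FormatError(f"duplicate {what}: {', '.join(map(str, dups))}")


def canonical_label_order(labels) -> list[str]:
    """Order labels by the fixed subtype vocabulary, unknown labels last."""
    labels = list(labels)
    known = [s for s in SUBTYPE_ORDER if s in labels]
    other = sorted(l for l in labels if l not in SUBTYPE_ORDER)
    return known + other


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression table with a scale tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample.  All
        entries must be finite; missing values are not permitted (drop
        incomplete genes upstream).
    scale
        One of :data:`SCALES`; ``counts`` additionally requires all
        entries to be non-negative.
    """

    data: pd.DataFrame
    scale: str = "log_generic"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise FormatError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                "non-finite value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        if self.scale == "counts" and values.size and (values < 0).any():
            raise FormatError("scale='counts' requires non-negative entries")

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        """Same gene/sample universe, new numeric content."""
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(df, scale or self.scale)


def read_expression_matrix(
    path, scale: str = "log_generic", transpose: bool = False
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first header cell ``gene_id``).

    Non-numeric cells and duplicate identifiers raise :class:`FormatError`
    naming the offending coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if raw.index.name != "gene_id":
        raise FormatError(
            f"{path}: first header cell must be 'gene_id', found {raw.index.name!r}"
        )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} (value {raw.iloc[i, j]!r})"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    if transpose:
        numeric = numeric.T
    return ExpressionMatrix(numeric, scale)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class AlignmentReport:
    """Outcome of restricting a matrix to a classifier's gene universe."""

    missing: list[str]
    n_retained: int
    n_params: int

    @property
    def n_missing(self) -> int:
        return len(self.missing)


def align_genes(matrix: ExpressionMatrix, params_genes) -> tuple[ExpressionMatrix, AlignmentReport]:
    """Restrict ``matrix`` to the genes of a parameter set, in parameter order.

    Returns the restricted matrix plus a report listing parameter genes
    absent from the data (a routine situation when a classifier gene is
    not on the assay panel).  Raises :class:`AlignmentError` when no gene
    is shared.
    """
    params = list(params_genes)
    _check_unique(params, "parameter gene ids")
    have = set(matrix.data.index)
    present = [g for g in params if g in have]
    missing = [g for g in params if g not in have]
    if not present:
        raise AlignmentError("no overlap between matrix genes and parameter genes")
    aligned = ExpressionMatrix(matrix.data.loc[present], matrix.scale)
    return aligned, AlignmentReport(missing=missing, n_retained=len(present), n_params=len(params))


# ---------------------------------------------------------------------------
# sample annotations


ANNOTATION_COLUMNS = ["cohort", "in_subgroup", "true_subtype"]


def make_annotations(sample_ids, cohort="cohort", in_subgroup=None, true_subtype=None) -> pd.DataFrame:
    """Build a sample-annotation table (index sample_id)."""
    _check_unique(sample_ids, "sample ids")
    n = len(sample_ids)
    df = pd.DataFrame(
        {
            "cohort": [cohort] * n if isinstance(cohort, str) else list(cohort),
            "in_subgroup": [False] * n if in_subgroup is None else list(in_subgroup),
            "true_subtype": [""] * n if true_subtype is None else list(true_subtype),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df["in_subgroup"] = df["in_subgroup"].astype(bool)
    return df


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    _check_unique(df.index, "sample ids")
    df.index = df.index.astype(str)
    df["in_subgroup"] = df["in_subgroup"].map(_parse_bool)
    df["true_subtype"] = df["true_subtype"].fillna("").astype(str)
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# centroid sets


@dataclass
class CentroidSet:
    """Prototype expression profiles, one column per subtype.

    ``method`` records which correlation the prototypes were trained
    for (``spearman`` for rank-based classification, ``pearson`` for
    scaled-expression classification).
    """

    data: pd.DataFrame  # genes x subtypes
    method: str = "spearman"

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "pearson"):
            raise FormatError(f"unknown correlation method {self.method!r}")
        labels = list(self.data.columns)
        _check_unique(labels, "subtype labels")
        unknown = [l for l in labels if l not in SUBTYPE_ORDER]
        if unknown:
            raise FormatError(f"unknown subtype labels: {unknown}; vocabulary is {SUBTYPE_ORDER}")
        if not 2 <= len(labels) <= 5:
            raise FormatError("centroid set must carry between 2 and 5 subtypes")
        _check_unique(self.data.index, "gene ids")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise FormatError("centroid values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subtype_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_centroid_set(path, method: str = "spearman") -> CentroidSet:
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if raw.index.name != "gene_id":
        raise FormatError(f"{path}: first header cell must be 'gene_id'")
    raw.index = raw.index.astype(str)
    return CentroidSet(raw.astype(float), method)


def write_centroid_set(centroids: CentroidSet, path) -> None:
    centroids.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# subtype calls


@dataclass
class SubtypeCallTable:
    """Per-sample subtype call with its full correlation (or posterior) profile.

    Columns of ``table``: ``call``, one ``rho_<subtype>`` per centroid,
    ``margin`` (largest minus second-largest score), ``tie`` and
    ``switched`` flags.  ``call`` equals the argmax label unless
    ``switched`` is set (second-centroid switching experiment).
    """

    table: pd.DataFrame
    subtypes: list[str]

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        needed = ["call", *(f"rho_{s}" for s in self.subtypes), "margin", "tie", "switched"]
        missing = [c for c in needed if c not in self.table.columns]
        if missing:
            raise FormatError(f"call table missing columns: {missing}")
        if (self.table["margin"].to_numpy() < -1e-12).any():
            raise FormatError("negative top-two margin")
        rho = self.correlations.to_numpy()
        if not np.isfinite(rho).all():
            raise FormatError("non-finite correlation value")
        # correlations live in [-1, 1]; posteriors (rules route) in [0, 1]
        if (rho < -1 - 1e-9).any() or (rho > 1 + 1e-9).any():
            raise FormatError("correlation outside [-1, 1]")
        self._check_argmax()

    def _check_argmax(self) -> None:
        rho = self.correlations.to_numpy()
        if not len(rho):
            return
        best = rho.max(axis=1)
        labels = np.asarray(self.subtypes)
        for i, (call, switched) in enumerate(
            zip(self.table["call"], self.table["switched"])
        ):
            if switched:
                continue
            near = set(labels[rho[i] >= best[i] - 1e-9])
            if call not in near:
                raise FormatError(
                    f"sample {self.table.index[i]!r}: call {call!r} is not a maximal score"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    @property
    def correlations(self) -> pd.DataFrame:
        return self.table[[f"rho_{s}" for s in self.subtypes]]

    @property
    def margin(self) -> pd.Series:
        return self.table["margin"]


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise FormatError(f"cannot parse boolean value {x!r}")


def write_calls(calls: SubtypeCallTable, path) -> None:
    out = calls.table.copy()
    out["tie"] = out["tie"].map(lambda b: "true" if b else "false")
    out["switched"] = out["switched"].map(lambda b: "true" if b else "false")
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_calls(path) -> SubtypeCallTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    subtypes = [c[len("rho_"):] for c in df.columns if c.startswith("rho_")]
    df["tie"] = df["tie"].map(_parse_bool)
    df["switched"] = df["switched"].map(_parse_bool)
    return SubtypeCallTable(df, subtypes)


# ---------------------------------------------------------------------------
# binary gene-pair rule sets


@dataclass
class RuleSet:
    """Ordered binary gene-pair rules with per-class conditional probabilities.

    A rule ``(gene_low, gene_high)`` is true within a sample iff
    ``expression(gene_low) < expression(gene_high)`` (strict; equality is
    false).  ``cond_prob[r, k]`` is the probability the rule is true in
    class ``k``; probabilities must be strictly inside (0, 1) — estimate
    them with additive smoothing.  ``priors`` sum to one.
    """

    rules: pd.DataFrame  # columns gene_low, gene_high
    cond_prob: pd.DataFrame  # rules x classes
    priors: pd.Series  # classes

    def __post_init__(self) -> None:
        if list(self.rules.columns[:2]) != ["gene_low", "gene_high"]:
            raise FormatError("rule table must start with columns gene_low, gene_high")
        if (self.rules["gene_low"] == self.rules["gene_high"]).any():
            raise FormatError("rule with gene_low == gene_high")
        if len(self.rules) != len(self.cond_prob):
            raise FormatError("rules and conditional probabilities differ in length")
        p = self.cond_prob.to_numpy(dtype=float)
        if p.size and ((p <= 0) | (p >= 1)).any():
            raise FormatError("conditional probabilities must lie strictly in (0, 1)")
        pri = self.priors.to_numpy(dtype=float)
        if (pri <= 0).any():
            raise FormatError("class priors must be positive")
        if abs(pri.sum() - 1.0) > 1e-9:
            raise FormatError(f"class priors sum to {pri.sum()!r}, expected 1")
        if list(self.cond_prob.columns) != list(self.priors.index):
            raise FormatError("conditional-probability classes and priors disagree")

    @property
    def classes(self) -> list[str]:
        return list(self.priors.index)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.rules["gene_low"]) | set(self.rules["gene_high"]))


def write_rule_set(rules: RuleSet, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#priors\t" + "\t".join(repr(float(p)) for p in rules.priors) + "\n")
        fh.write("gene_low\tgene_high\t" + "\t".join(rules.classes) + "\n")
        for (low, high), (_, probs) in zip(
            rules.rules[["gene_low", "gene_high"]].itertuples(index=False),
            rules.cond_prob.iterrows(),
        ):
            fh.write(f"{low}\t{high}\t" + "\t".join(repr(float(v)) for v in probs) + "\n")


def read_rule_set(path) -> RuleSet:
    path = Path(path)
    priors_vals = None
    rows = []
    header = None
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#priors\t"):
                priors_vals = [float(v) for v in line.split("\t")[1:]]
                continue
            if line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(line.split("\t"))
    if header is None or priors_vals is None:
        raise FormatError(f"{path}: missing header or '#priors' line")
    classes = header[2:]
    if len(priors_vals) != len(classes):
        raise FormatError(f"{path}: priors length does not match class columns")
    rules = pd.DataFrame([r[:2] for r in rows], columns=["gene_low", "gene_high"])
    try:
        probs = pd.DataFrame(
            [[float(v) for v in r[2:]] for r in rows], columns=classes
        )
    except ValueError as exc:
        raise FormatError(f"{path}: malformed probability value ({exc})") from exc
    priors = pd.Series(priors_vals, index=classes, dtype=float)
    return RuleSet(rules, probs, priors)


# ---------------------------------------------------------------------------
# reports


def write_report(report: dict, path) -> None:
    """Serialize a concordance/pipeline report to JSON (sorted keys)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
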