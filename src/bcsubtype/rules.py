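"""Single-sample subtyping from binary gene-pair rules.

Each rule compares two genes *within* a sample — true iff
``expression(gene_low) < expression(gene_high)`` (strict; equality is
false) — so the rule profile depends only on the within-sample ordering
of genes.  Calls therefore survive any strictly monotone per-sample
transform, which is what makes this family of classifiers "absolute":
no cohort-level normalization is needed.  The decision is naive Bayes
over the rule indicators with additively smoothed per-class conditional
probabilities and (by default uniform) class priors.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import ExpressionMatrix, FormatError, RuleSet, SubtypeCallTable


class RuleError(ValueError):
    """Rule evaluation/training received unusable input."""


def evaluate_rules(matrix: ExpressionMatrix, rules: RuleSet) -> pd.DataFrame:
    """Evaluate every rule in every sample -> boolean rules x samples frame."""
    have = set(matrix.data.index)
    missing = sorted(set(rules.genes) - have)
    if missing:
        raise RuleError(f"rule gene(s) absent from matrix: {', '.join(missing)}")
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    v = matrix.values
    low = np.array([pos[g] for g in rules.rules["gene_low"]])
    high = np.array([pos[g] for g in rules.rules["gene_high"]])
    binary = v[low] < v[high]
    return pd.DataFrame(binary, columns=matrix.sample_ids)


def nb_classify(binary: pd.DataFrame, rules: RuleSet) -> SubtypeCallTable:
    """Naive-Bayes subtype call from a rule-indicator matrix.

    Per sample and class k:
    ``log posterior_k = log prior_k + sum_r [b_r log p_rk + (1-b_r) log(1-p_rk)]``,
    normalized so posteriors sum to one.  The posterior vector plays the
    role of the correlation profile in the resulting call table; the
    margin is the top-two posterior gap.
    """
    if len(binary) != rules.n_rules:
        raise RuleError("indicator matrix and rule set differ in rule count")
    p = rules.cond_prob.to_numpy(dtype=float)  # rules x classes
    if ((p <= 0) | (p >= 1)).any():
        raise RuleError("conditional probabilities must be smoothed away from 0/1")
    b = binary.to_numpy(dtype=float)  # rules x samples
    logp = b.T @ np.log(p) + (1 - b).T @ np.log1p(-p)  # samples x classes
    logp += np.log(rules.priors.to_numpy(dtype=float))[None, :]
    post = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    classes = rules.classes
    best = post.max(axis=1)
    second = np.partition(post, -2, axis=1)[:, -2] if post.shape[1] >= 2 else best
    order = {c: i for i, c in enumerate(classes)}
    calls, ties = [], []
    for i in range(post.shape[0]):
        near = np.flatnonzero(post[i] >= best[i] - 1e-12)
        ties.append(len(near) > 1)
        calls.append(classes[min(near, key=lambda k: order[classes[k]])])
    table = pd.DataFrame(
        {"call": calls}, index=pd.Index(binary.columns, name="sample_id")
    )
    for k, lab in enumerate(classes):
        table[f"rho_{lab}"] = post[:, k]
    table["margin"] = best - second
    table["tie"] = ties
    table["switched"] = False
    return SubtypeCallTable(table, classes)


def classify_rules(matrix: ExpressionMatrix, rules: RuleSet) -> SubtypeCallTable:
    """Convenience: evaluate rules then apply the naive-Bayes decision."""
    return nb_classify(evaluate_rules(matrix, rules), rules)


def subset_rules(rules: RuleSet, available_genes) -> tuple[RuleSet, dict]:
    """Keep only rules whose both genes sit on the available panel.

    Mirrors applying a genome-wide rule list to a targeted assay panel,
    where typically only a fraction of the rules remain evaluable.
    """
    have = set(available_genes)
    keep = rules.rules["gene_low"].isin(have) & rules.rules["gene_high"].isin(have)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise RuleError("no rule has both genes on the available panel")
    sub = RuleSet(
        rules.rules.loc[keep].reset_index(drop=True),
        rules.cond_prob.loc[keep.to_numpy()].reset_index(drop=True),
        rules.priors,
    )
    return sub, {"n_retained": n_keep, "n_total": rules.n_rules}


def train_rules(
    reference: ExpressionMatrix,
    labels,
    n_rules: int = 50,
    smoothing: float = 1.0,
    n_candidate_genes: int = 40,
    uniform_priors: bool = True,
) -> RuleSet:
    """Select discriminative gene-pair rules from a labelled reference cohort.

    Candidate pairs are drawn from the ``n_candidate_genes`` most
    variable genes; pairs are ranked by the mutual information between
    the rule indicator and the class label and the top ``n_rules`` are
    kept (ties broken by gene order, so training is deterministic).
    Conditional probabilities use additive smoothing; priors default to
    uniform so the assignment does not encode cohort composition.
    """
    y = pd.Series(list(labels), index=reference.sample_ids)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise RuleError("training needs at least 2 classes")
    counts = y.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise RuleError(f"class(es) with fewer than 2 samples: {small}")
    if smoothing <= 0:
        raise RuleError("smoothing must be positive")
    v = reference.values
    var = v.var(axis=1)
    top = np.argsort(-var, kind="stable")[: min(n_candidate_genes, reference.n_genes)]
    top = np.sort(top)  # deterministic gene order
    genes = [reference.gene_ids[i] for i in top]
    pairs = list(combinations(range(len(top)), 2))
    sub = v[top]
    b = np.array([sub[i] < sub[j] for i, j in pairs])  # pairs x samples
    # mutual information I(rule; class) from joint counts
    n = len(y)
    y_codes = y.map({c: k for k, c in enumerate(classes)}).to_numpy()
    mi = np.zeros(len(pairs))
    for k in range(len(classes)):
        in_k = y_codes == k
        n_k = in_k.sum()
        for bit in (0, 1):
            joint = ((b[:, in_k] == bit).sum(axis=1)) / n
            marg_b = (b == bit).sum(axis=1) / n
            with np.errstate(divide="ignore", invalid="ignore"):
                term = joint * np.log(joint / (marg_b * (n_k / n)))
            mi += np.where(joint > 0, term, 0.0)
    order = sorted(range(len(pairs)), key=lambda r: (-mi[r], pairs[r]))
    chosen = order[: min(n_rules, len(pairs))]
    rule_rows = [(genes[pairs[r][0]], genes[pairs[r][1]]) for r in chosen]
    cond = np.empty((len(chosen), len(classes)))
    for k in range(len(classes)):
        in_k = y_codes == k
        n_k = in_k.sum()
        cond[:, k] = (b[chosen][:, in_k].sum(axis=1) + smoothing) / (n_k + 2 * smoothing)
    priors = (
        np.full(len(classes), 1.0 / len(classes))
        if uniform_priors
        else counts.reindex(classes).to_numpy() / n
    )
    return RuleSet(
        pd.DataFrame(rule_rows, columns=["gene_low", "gene_high"]),
        pd.DataFrame(cond, columns=classes),
        pd.Series(priors, index=classes),
    )
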