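"""End-to-end comparison runs: two classification pipelines, one report.

A comparison configuration names an expression input and two pipelines
(each an ordered normalization chain plus a classifier); the run emits
per-pipeline calls, the cross-method contingency table, agreement,
Cohen's kappa (with a configurable label merge map), conditional
misassignment rates, subtype distributions, the clear-defined/discord
partition, top-two margins and the second-centroid switching audit.
Every output is also written as TSV; the report is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io
from .centroid import (
    ClassifierConfig,
    adjacency_audit,
    classify,
    switch_to_second,
    top_two,
)
from .concordance import ConcordanceError, concordance_report
from .normalization import (
    apply_technical_calibration,
    housekeeping_normalize,
    log2_cpm,
    median_center,
    quantile_normalize,
    read_calibration,
    read_reference,
    sgmd_center,
    sgpct_center,
)
from .rules import classify_rules


class PipelineError(ValueError):
    """A comparison configuration is incomplete or inconsistent."""


def _apply_normalization_step(matrix: io.ExpressionMatrix, step: dict) -> io.ExpressionMatrix:
    op = step.get("op")
    if op == "log2_cpm":
        return log2_cpm(matrix)
    if op == "quantile_normalize":
        return quantile_normalize(matrix)
    if op == "median_center":
        return median_center(matrix)
    if op == "housekeeping_normalize":
        return housekeeping_normalize(matrix, step["genes"])
    if op == "sgpct_center":
        return sgpct_center(matrix, read_reference(step["reference"]))
    if op == "sgmd_center":
        return sgmd_center(matrix, read_reference(step["reference"]))
    if op == "technical_calibration":
        return apply_technical_calibration(matrix, read_calibration(step["factors"]))
    raise PipelineError(f"unknown normalization op {op!r}")


def run_pipeline(matrix: io.ExpressionMatrix, spec: dict) -> io.SubtypeCallTable:
    """Apply one pipeline (normalization chain + classifier) to a matrix."""
    for step in spec.get("normalization", []):
        matrix = _apply_normalization_step(matrix, step)
    kind = spec.get("classifier", "centroid")
    if kind == "centroid":
        centroids = io.read_centroid_set(
            spec["centroids"], spec.get("method", "spearman")
        )
        config = ClassifierConfig(
            method=spec.get("method", centroids.method),
            min_genes=spec.get("min_genes", 3),
            switch_threshold=spec.get("switch_threshold", 0.1),
        )
        return classify(matrix, centroids, config)
    if kind == "rules":
        return classify_rules(matrix, io.read_rule_set(spec["rules"]))
    raise PipelineError(f"unknown classifier kind {kind!r}")


def run_comparison(config: dict, out_dir=None) -> dict:
    """Execute a two-pipeline comparison and build the report bundle."""
    pipelines = config.get("pipelines", [])
    if len(pipelines) != 2:
        raise PipelineError("comparison config must name exactly two pipelines")
    matrix = io.read_expression_matrix(
        config["input"]["expression"], config["input"].get("scale", "log_generic")
    )
    names = [p.get("name", f"pipeline_{i}") for i, p in enumerate(pipelines)]
    calls = [run_pipeline(matrix, p) for p in pipelines]
    if calls[0].sample_ids != calls[1].sample_ids:
        raise PipelineError("pipelines produced calls over different sample sets")
    merge_map = config.get("merge_map") or None
    try:
        report = concordance_report(
            calls[0], calls[1], merge_map, name_a=names[0], name_b=names[1]
        )
    except ConcordanceError as exc:
        raise PipelineError(str(exc)) from exc

    threshold = float(config.get("switch_threshold", 0.1))
    margins = [top_two(c) for c in calls]
    switched, summary = switch_to_second(calls[0], threshold)
    try:
        audit, audit_summary = adjacency_audit(calls[0], switched)
        audit_err = None
    except Exception as exc:  # labels outside the linear order (e.g. NL)
        audit, audit_summary, audit_err = None, None, str(exc)
    report["switch"] = {
        "pipeline": names[0],
        "threshold": threshold,
        "n_switched": summary.n_switched,
        "fraction": summary.fraction,
        "adjacency": audit_summary,
        "adjacency_error": audit_err,
    }
    report["top_two_margin_medians"] = {
        name: float(m["delta"].median()) for name, m in zip(names, margins)
    }
    report["config"] = {k: v for k, v in config.items() if k != "input"} | {
        "input": {str(k): str(v) for k, v in config["input"].items()}
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, c, m in zip(names, calls, margins):
            io.write_calls(c, out / f"calls_{name}.tsv")
            m.to_csv(out / f"top_two_{name}.tsv", sep="\t", index_label="sample_id")
        io.write_calls(switched, out / f"calls_{names[0]}_switched.tsv")
        if audit is not None:
            audit.to_csv(out / "switch_audit.tsv", sep="\t", index=False)
        pd.DataFrame(
            report["contingency"]["counts"],
            index=report["contingency"]["labels_a"],
            columns=report["contingency"]["labels_b"],
        ).to_csv(out / "contingency.tsv", sep="\t", index_label="method_a\\method_b")
        io.write_report(report, out / "report.json")
    return report
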