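"""Packaged contingency-table fixtures from the published trial comparisons.

Two cross-classification tables ship with the package:

* ``paloma2_table1`` — advanced-breast-cancer trial, n = 222: gene-pair
  rule calls on a targeted panel (rows) against the clinical
  four-subtype centroid assay (columns).
* ``pallet_table2`` — neoadjuvant trial, n = 224: gene-pair rule calls
  on whole-transcriptome RNA-seq (rows) against PAM50 with
  subgroup-median centering plus technical calibration (columns).

Only the published cross-tabulations are bundled; the underlying
expression data are available on request from the sponsor and are not
redistributed here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .concordance import ContingencyTable


def _load_table(name: str) -> ContingencyTable:
    ref = resources.files("bcsubtype").joinpath(f"data/{name}.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "method_a"
    df.columns.name = "method_b"
    return ContingencyTable(df)


def load_paloma2_table1() -> ContingencyTable:
    """Rule-based (rows, 5 subtypes) vs clinical centroid assay (columns, 4)."""
    return _load_table("paloma2_table1")


def load_pallet_table2() -> ContingencyTable:
    """Rule-based (rows) vs centroid sgMd.TC route (columns), 5 subtypes each."""
    return _load_table("pallet_table2")
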