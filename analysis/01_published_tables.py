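"""Concordance statistics from the published cross-tabulations.

Recomputes, from the packaged contingency-table fixtures, everything the
two trial comparisons report: overall agreement, Cohen's kappa after
merging normal-like into luminal A, column-conditional misassignment
rates, and per-method subtype distributions.  Writes
results/published_concordance.json and a rates table per trial.
"""

from pathlib import Path

import bcsubtype as bc
from bcsubtype.concordance import calls_from_contingency, concordance_report
from bcsubtype.datasets import load_paloma2_table1, load_pallet_table2
from bcsubtype.io import write_report

RESULTS = Path(__file__).resolve().parents[1] / "results"


def analyse(name: str, table, merge_map) -> dict:
    calls_a, calls_b = calls_from_contingency(table)
    report = concordance_report(calls_a, calls_b, merge_map, name_a="rules", name_b="centroid")
    rates = bc.conditional_rates(table, axis="columns")
    rates["percent"].to_csv(RESULTS / f"{name}_conditional_rates_pct.tsv", sep="\t")
    print(
        f"{name}: n={report['n']}, agreement {report['agreement']['percent']}% "
        f"({report['n_clear_defined']}/{report['n']} clear-defined), "
        f"kappa {report['kappa']['rounded']} (merge {merge_map})"
    )
    return report


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    t1 = load_paloma2_table1()
    t2 = load_pallet_table2()
    combined = {
        "paloma2": analyse("paloma2", t1, {"NL": "LumA"}),
        "pallet": analyse("pallet", t2, None),
    }
    r1 = bc.conditional_rates(t1)
    print(
        "paloma2 highlights: "
        f"{r1['percent'].loc['LumA', 'LumB']}% of centroid-LumB called LumA by rules; "
        f"{r1['percent'].loc['HER2-E', 'BL']}% of centroid-BL called HER2-E."
    )
    r2 = bc.conditional_rates(t2)
    print(
        "pallet highlights: "
        f"{r2['percent'].loc['LumB', 'LumA']}% of centroid-LumA called LumB, "
        f"{r2['percent'].loc['NL', 'LumA']}% called NL by rules."
    )
    write_report(combined, RESULTS / "published_concordance.json")
    print(f"wrote {RESULTS / 'published_concordance.json'}")


if __name__ == "__main__":
    main()
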