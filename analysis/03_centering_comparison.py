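"""Cohort-bias centering versus classification accuracy.

On the synthetic biased trial, compares truth-recovery accuracy of
Spearman nearest-centroid calls under three per-gene centering schemes
(naive within-trial median, subgroup percentile sgPct, subgroup median
plus technical calibration sgMd.TC), on the clean and on the
platform-distorted trial; repeats the naive-vs-sgPct contrast over ten
independent scenario draws; and traces cross-platform call discordance
(Cohen's kappa) over a grid of platform-bias magnitudes.
"""

from pathlib import Path

import pandas as pd

from bcsubtype.simulate import (
    SimulationConfig,
    centering_accuracy,
    centering_experiment,
    kappa_vs_bias,
    make_trial_scenario,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    scenario = make_trial_scenario(SimulationConfig(seed=SEED))

    rows = []
    for platform in ("clean", "distorted"):
        acc = centering_accuracy(scenario, platform=platform)
        for scheme, a in acc.items():
            rows.append({"platform": platform, "scheme": scheme, "accuracy": round(a, 4)})
    single = pd.DataFrame(rows)
    single.to_csv(RESULTS / "centering_accuracy.tsv", sep="\t", index=False)
    print("single-draw truth-recovery accuracy:")
    print(single.pivot(index="scheme", columns="platform", values="accuracy"))

    exp = centering_experiment(SimulationConfig(seed=SEED), n_seeds=10)
    exp.round(4).to_csv(RESULTS / "centering_accuracy_10seeds.tsv", sep="\t")
    gap = (exp["sgpct"] - exp["naive"]).mean()
    print(
        f"\n10-seed means: naive {exp['naive'].mean():.3f}, sgpct {exp['sgpct'].mean():.3f} "
        f"(sgPct recovers +{100 * gap:.1f} accuracy points on the biased cohort)"
    )

    kb = kappa_vs_bias(SimulationConfig(seed=SEED, n_trial=150))
    kb.round(4).to_csv(RESULTS / "kappa_vs_platform_bias.tsv", sep="\t", index=False)
    print("\ncross-platform call agreement (kappa) vs bias magnitude:")
    print(kb.to_string(index=False))
    print("discordance grows as the platform distortion grows.")


if __name__ == "__main__":
    main()
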