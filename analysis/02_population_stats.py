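"""Population statistics over the simulated cohorts.

From the per-neuron rate table of 01_simulate_cohort.py: percentage of
hyperactive cells per subject and condition, paired subject-level Wilcoxon
tests (baseline vs application vs washout in the treated cohort), activity
normalized to baseline, and Kolmogorov-Smirnov comparisons of the pooled
neuronal rate distributions against wild-type.

Writes results/hyperactivity_summary.csv and results/population_stats.json
"""

import json
from pathlib import Path

import pandas as pd

from abquant.stats import compare, fraction_hyperactive

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = pd.read_csv(RESULTS / "cohort_neuron_rates.csv")

    summary = (
        df.groupby(["genotype", "treatment", "condition", "subject_id"])
        .agg(mean_rate=("rate_per_min", "mean"),
             pct_hyperactive=("rate_per_min", lambda r: fraction_hyperactive(rates=r)))
        .reset_index()
    )
    summary.to_csv(RESULTS / "hyperactivity_summary.csv", index=False,
                   float_format="%.3f")

    treated = summary[summary.treatment == "anticalin"].pivot_table(
        index="subject_id", columns="condition", values="mean_rate")
    stats = {
        "treated_baseline_vs_application": vars(
            compare([treated["baseline"], treated["application"]], "paired")),
        "treated_baseline_vs_washout": vars(
            compare([treated["baseline"], treated["washout"]], "paired")),
    }
    norm = 100 * treated["application"] / treated["baseline"]
    stats["treated_normalized_application_pct"] = {
        "mean": float(norm.mean()), "sem": float(norm.sem())}

    def pooled(genotype, treatment, condition):
        sel = df[(df.genotype == genotype) & (df.treatment == treatment)
                 & (df.condition == condition)]
        return sel["rate_per_min"].to_numpy()

    untreated = pooled("APP23xPS45", "vehicle", "baseline")
    wt = pooled("wild-type", "vehicle", "baseline")
    treated_app = pooled("APP23xPS45", "anticalin", "application")
    stats["ks_untreated_vs_wildtype"] = vars(compare([untreated, wt], "distribution"))
    stats["ks_treated_application_vs_wildtype"] = vars(
        compare([treated_app, wt], "distribution"))

    for k, v in stats.items():
        if isinstance(v, dict) and "p_value" in v:
            v.pop("posthoc", None)
            print(f"{k}: {v['test']} p = {v['p_value']:.4g}")
        else:
            print(f"{k}: {v}")
    (RESULTS / "population_stats.json").write_text(
        json.dumps(stats, indent=2, default=str) + "\n")

    base = summary[summary.condition == "baseline"]
    print("\nbaseline % hyperactive (mean over subjects):")
    print(base.groupby(["genotype", "treatment"])["pct_hyperactive"].mean().round(1))


if __name__ == "__main__":
    main()
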