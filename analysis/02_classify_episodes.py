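#!/usr/bin/env python
"""Classify every episode into its RUG-III/HC group and tabulate the mix.

Reads the cohort written by 01_simulate_cohort.py, runs the hierarchical
grouper with the default rule configuration, and writes the episode->group
map plus the full-sample distribution table (category and group counts with
percentages) under results/.
"""

import pandas as pd

from rughc import classify_frame, default_rules, distribution_table, read_cohort

OUTDIR = "results"


def main() -> None:
    rules = default_rules()
    cohort = read_cohort("results/data/assessments.csv", "results/data/billing.csv", rules)
    groups = classify_frame(cohort.assessments, rules)
    groups.to_csv(f"{OUTDIR}/episode_groups.csv")

    table = distribution_table(groups.tolist())
    table.to_csv(f"{OUTDIR}/distribution_full.csv", index=False)

    cats = table[table.level == "category"].sort_values("percentage", ascending=False)
    print(f"classified {len(groups)} episodes -> {OUTDIR}/episode_groups.csv")
    print("category mix (full sample):")
    with pd.option_context("display.float_format", "{:.1f}".format):
        print(cats[["label", "count", "percentage"]].to_string(index=False))
    top = table[table.level == "group"].nlargest(3, "percentage")
    print("largest groups:", ", ".join(
        f"{r.label} {r.percentage:.1f}%" for r in top.itertuples()))


if __name__ == "__main__":
    main()
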