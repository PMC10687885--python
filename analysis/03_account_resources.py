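#!/usr/bin/env python
"""Per-episode resource accounting and the operational-sample trim.

Computes paid hours, PSW-standardized paid cost, estimated unpaid hours
(3-day self-reports scaled to the episode) and the combined measures for
every billing-complete episode, then derives the operational sample by
removing the shortest 1% and longest 5% of episodes. Writes the full and
operational episode-measure tables under results/.
"""

import pandas as pd

from rughc import default_weights, episode_measures, read_cohort, trim_operational

OUTDIR = "results"


def main() -> None:
    cohort = read_cohort("results/data/assessments.csv", "results/data/billing.csv")
    groups = pd.read_csv(f"{OUTDIR}/episode_groups.csv").set_index("episode_id")["group"]
    weights = default_weights()

    measures, n_missing = episode_measures(cohort.assessments, cohort.billing, weights)
    measures = measures.merge(groups, left_on="episode_id", right_index=True)
    measures.to_csv(f"{OUTDIR}/measures_full.csv", index=False)

    operational = trim_operational(cohort.assessments, 0.01, 0.05)
    kept = measures[measures["episode_id"].isin(set(operational["episode_id"]))]
    kept.to_csv(f"{OUTDIR}/measures_operational.csv", index=False)

    n_all = len(cohort.assessments)
    print(f"billing-complete episodes: {len(measures)} of {n_all} "
          f"({n_missing} lack billing records)")
    print(f"operational sample: {len(operational)} of {n_all} episodes "
          f"({100 * (n_all - len(operational)) / n_all:.2f}% trimmed); "
          f"{len(kept)} with complete billing")
    print(f"paid care:   mean {measures['paid_hours'].mean():.1f} h/episode "
          f"(SD {measures['paid_hours'].std(ddof=1):.1f})")
    print(f"unpaid care: mean {measures['unpaid_hours'].mean():.1f} h/episode "
          f"(SD {measures['unpaid_hours'].std(ddof=1):.1f})")
    print(f"-> {OUTDIR}/measures_full.csv, {OUTDIR}/measures_operational.csv")


if __name__ == "__main__":
    main()
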