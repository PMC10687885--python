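#!/usr/bin/env python
"""Generate the working synthetic cohort of transitional home-care episodes.

1,680 episodes across 8 programs, with the documented episode-length,
discipline-hours, unpaid-care and case-mix structure; roughly a quarter of
episodes lack billing records and a fifth lack the discharge self-report.
Writes assessments.csv and billing.csv under results/data/.
"""

from rughc import CohortConfig, generate_cohort, write_cohort

SEED = 20260927
OUTDIR = "results/data"


def main() -> None:
    config = CohortConfig(n_episodes=1680, seed=SEED)
    assessments, billing = generate_cohort(config)
    paths = write_cohort(assessments, billing, OUTDIR)

    n_billed = assessments["episode_id"].isin(set(billing["episode_id"])).sum()
    print(f"cohort: {len(assessments)} episodes, {len(billing)} billing rows -> {OUTDIR}/")
    print(f"episode length: mean {assessments['episode_days'].mean():.1f} d "
          f"(SD {assessments['episode_days'].std(ddof=1):.1f}), "
          f"range {assessments['episode_days'].min()}-{assessments['episode_days'].max()}")
    print(f"billing-complete episodes: {n_billed} "
          f"({100 * n_billed / len(assessments):.1f}%)")
    print(f"discharge self-report present: "
          f"{assessments['unpaid_hours_3day_discharge'].notna().sum()}")
    print(f"files: {paths['assessments']}, {paths['billing']}")


if __name__ == "__main__":
    main()
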