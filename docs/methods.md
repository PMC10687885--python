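# Methods

This note documents the models, defaults and design choices behind the
package, and what the synthetic-data tests do and do not establish about
real cohorts.

## The classification model

RUG-III/HC is a hierarchical case-mix system: seven clinical categories in
fixed priority order (Rehabilitation, Extensive services, Special care,
Clinically complex, Impaired cognition, Behaviour problems, Reduced physical
functions), subdivided into 23 groups — (3, 3, 2, 4, 3, 3, 5) per category —
by functional status. The algorithmic skeleton implemented here is exact:
triggers are evaluated in rank order, the first hit fixes the category, the
category's split map fixes the group, and the terminal category is
always-true, so classification is total and exclusive over valid records.

The *content* of the triggers and splits is configuration
(`src/rughc/data/rules_default.yaml`), because the original grouper's
item-level definitions are external to this implementation. The shipped
defaults use one flag or score per trigger class:

- Rehabilitation: ≥ 120 therapy minutes in 7 days;
- Extensive services: any of {IV medication, tracheostomy care, ventilator},
  with the SE3/SE2/SE1 split on the count of distinct extensive services
  (≥3 / 2 / 1) — a three-way split needs a non-ADL discriminator;
- Special care and Clinically complex: named clinical-flag lists;
- Impaired cognition: cognitive performance score ≥ 3;
- Behaviour problems: any behaviour flag;
- Reduced physical functions: catch-all.

The ADL scale is a 4-item sum (eating, transfer, toilet use, locomotion;
codes 1–5, unit weights) banded A ≤ 7 < B ≤ 12 < C ≤ 16 < D, so band A is
"low ADL limitation". The IADL scale (meal preparation, housework, finances;
codes 0–3) reports "some" difficulty iff any item codes ≥ 1. The `*A1`
groups mean low ADL *and* no IADL difficulty; `*A2` low ADL with some IADL
difficulty. These cut-points are config values, and config validation
enforces the structural invariants (canonical categories in order, total
split maps, terminal catch-all). Anyone with access to the original
item-level definitions can encode them in the same YAML without touching
code. Records with missing or out-of-range items raise a classification
error rather than being imputed, mirroring the exclusion of incomplete
assessments in practice.

## Resource accounting

- **Standardized cost weights.** Each discipline's hourly rate is divided by
  the PSW rate, making weight(PSW) = 1 exactly and rendering every cost in
  PSW-hour equivalents. Costs are therefore invariant to rescaling all rates
  by a common factor, and no currency appears downstream. The shipped rate
  card is synthetic (a realistic Ontario-style fee schedule); only its
  ratios matter.
- **Unpaid care.** Clients self-report unpaid-care hours over the preceding
  3 days at admission and discharge. The per-episode estimate is
  mean(adm, dis)/3 × episode days, falling back to the admission report
  alone when the discharge assessment is missing. The division by 3 is
  forced by magnitudes: ~10.6 h per 3-day report at ~99.5 days/episode gives
  ~350 h/episode, the documented order. Unpaid hours are valued at the full
  PSW replacement weight (1.00 by default, configurable).
- **Trimming.** The operational sample removes episodes strictly below the
  1% quantile or strictly above the 95% quantile of episode length.
  Quantiles use numpy's inclusive linear interpolation; the convention is a
  parameter because published sample counts cannot pin it down. On the
  explicit 1..100-day vector this removes day 1 and days 96–100 (94
  retained).
- Episodes without billing records are excluded from cost and CMI
  computation but retained for classification and distribution tables.

## Case-mix indices and CVs

CMI_gm = mean_gm / overall-mean_m; CV_gm = SD_gm / mean_gm. SDs are sample
SDs (n−1 denominator; a `ddof` flag selects the population convention, which
published tables do not disambiguate). Single-member groups report SD 0 by
convention; empty groups report NA and are excluded consistently from the
weighted-mean identity Σ n_g·CMI_gm = N. Tables are rendered to 2 decimals
with full precision retained in machine-readable output; groups with n < 10
carry an instability flag.

## Variance explained

"Utilization as a function of the CMIs" is implemented as four separate
simple regressions — each measure on its own group CMI — matching a
one-R²-per-measure layout (a joint four-predictor model would yield a single
R²). The program indicator enters as dummy variables with the largest
program as reference (arbitrary but deterministic). R² is unadjusted OLS
(statsmodels). Two identities are enforced by tests: adding the program
indicator never decreases R² (nesting), and on the sample used to derive the
CMIs the CMI-only R² equals between-group SS / total SS (eta-squared),
because the fitted regression on a group-mean-derived predictor recovers the
group means. CMIs are refit within each sample before fitting by default
(`refit_cmi=False` reuses the full-sample CMIs; which the original analysis
did is not documented, so both are selectable).

## The synthetic cohort generator

The generator is the package's stand-in for the non-public study data. Its
defaults *are* the documented cohort structure:

- episode lengths: truncated normal, mean 99.49 d, SD 35.90 d, range
  [3, 622];
- category mix (0.104, 0.003, 0.058, 0.416, 0.020, 0.021, 0.378) in
  hierarchy order, with within-category group shares from the published
  23-group distribution;
- nine disciplines with PSW-dominated hours: per-discipline use
  probabilities and conditional log-normal hours whose products match the
  documented per-episode means (e.g. PSW 0.95 × 43.5 h);
- unpaid 3-day reports: a correlated log-normal pair (mean 10.6 h, SD 14 h,
  admission–discharge correlation 0.8 — reports are known to be stable
  within an episode);
- missing billing for 25.5% of episodes and missing discharge reports for
  20%, removed independently per episode;
- per-group multiplicative effects on expected hours, with *separate*
  profiles for paid care (paid-time CMI scale, range 0.68–2.07) and unpaid
  care (combined-time CMI scale, range 0.51–3.06). The separation matters:
  unpaid care is far more strongly differentiated across groups than paid
  care in the observed cohort, and it is what makes the combined measures
  better explained than the paid-only ones. Groups unobserved in the
  reference distribution (SE3, SE1, IA1) carry rank-consistent stand-in
  effects;
- optional per-program multipliers on paid care (default: all 1) to study
  program-level heterogeneity.

Construction is *planting*: the sampled group's triggers and band
requirements are written into the assessment (higher-priority triggers
cleared, lower-priority ones sprinkled in at 15% for realism — the
hierarchy makes them inert), and the generator classifies its own output as
a self-check, so sampled and assigned groups agree exactly. Paid and unpaid
hours both scale linearly with episode length, so length outliers are
utilization outliers — which is why trimming raises R², as observed.

What the generator does **not** emulate: diagnosis co-occurrence,
within-episode time profiles of care delivery, program-specific case-mix
(programs differ only through the optional paid-care multipliers),
correlation between missingness and clinical status, and any real
item-level response process. Passing tests therefore establish the
correctness and internal consistency of the pipeline — classification
fidelity to the rule table, accounting identities, CMI normalization,
eta-squared equivalence, recovery of known effects — not the empirical
validity of the default rule thresholds for any real population.

## Numerical choices and degenerate inputs

- Determinism: all randomness flows from `numpy.random.default_rng` seeded
  via `SeedSequence([seed, stream])`, with a separate stream for
  missingness; identical configs give byte-identical CSVs.
- Log-normals are parameterized by arithmetic mean and SD
  (σ² = ln(1 + (SD/mean)²)), so configured means are exact expectations.
- All-zero inputs: CV of an all-zero vector is 0 by convention; empty
  billing yields (0, 0) paid measures; an all-missing-billing cohort
  degrades to distribution tables plus empty case-mix/evaluation outputs
  with a warning.
- Constant predictors or outcomes raise a model error (rank check before
  OLS) rather than returning a meaningless R².
- Problem sizes in tests: routine checks run on 200–2,000-episode cohorts;
  the parameter-recovery check uses 10,000 episodes and 3-SE Monte-Carlo
  bands; the grouper is verified against a brute-force oracle on an
  exhaustive ~3,000-case grid of trigger subsets × ADL bands × IADL bands.

## Known limitations

- The default clinical triggers and split thresholds are documented
  placeholders faithful to the hierarchy's *shape*; fidelity to the original
  grouper's item logic requires encoding its published definitions into the
  rule YAML.
- Whether group IA1 is structurally unreachable under the original rules
  cannot be decided from the available material; under the shipped defaults
  it is reachable (cognition ≥ 3, band A, no IADL difficulty).
- The cohort size is a free parameter: published tables report slightly
  different episode totals (1,804 vs 1,680) depending on the inclusion
  criterion, and the drivers use 1,680 (the classified sample).
- CMIs are point estimates; no uncertainty intervals are produced.
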