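"""Synthetic transitional home-care cohorts with known ground truth.

The study's assessment and billing data are not public, so every downstream
stage is exercised on generated cohorts that reproduce the documented
structure of the real one: episode lengths from a truncated normal
(mean 99.49 d, SD 35.90 d, range 3-622 d), nine provider disciplines with
PSW-dominated paid hours (~74 h/episode), heavy-tailed unpaid care
(~10.6 h per 3-day self-report, hence ~350 h/episode), a category mix
concentrated in Clinically complex and Reduced physical functions, and
missing billing for roughly a quarter of episodes.

The generator samples a target group for each episode and *plants* exactly
the assessment items that make the configured grouper assign that group:
the category's trigger (clearing all higher-priority triggers), an ADL item
vector inside the band the group's split rule requires, and matching IADL
codes. Lower-priority triggers are sprinkled in at random for realism; they
cannot change the outcome because the hierarchy resolves top-down. Expected
paid hours scale multiplicatively with the per-group paid-care effect, the
per-program effect and episode length; unpaid hours follow their own
per-group effect profile (in the observed cohort, unpaid care is far more
strongly differentiated across groups than paid care). The configured
relative effects are therefore the cohort's true case-mix indices.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, model_validator
from scipy.stats import truncnorm

from .errors import ConfigurationError
from .records import join_flags, record_from_row
from .reference import (
    REFERENCE_CATEGORY_MIX,
    REFERENCE_GROUP_COUNTS_FULL,
    REFERENCE_GROUP_EFFECTS,
    REFERENCE_UNPAID_GROUP_EFFECTS,
)
from .rules import RuleConfig, default_rules
from .taxonomy import CATEGORY_GROUPS, CATEGORY_ORDER, DISCIPLINES, GROUP_ORDER

__all__ = ["LengthModel", "DisciplineModel", "UnpaidModel", "CohortConfig",
           "generate_cohort", "inject_missingness"]

ASSESSMENT_COLUMNS_FIXED = [
    "episode_id", "client_id", "program_id", "episode_start", "episode_end",
    "episode_days", "cognitive_performance", "behaviour_flags", "clinical_flags",
    "therapy_minutes_7day", "unpaid_hours_3day_admission",
    "unpaid_hours_3day_discharge", "age", "sex", "sampled_group",
]


class LengthModel(BaseModel):
    """Truncated-normal episode length in days."""

    mean: float = 99.49
    sd: float = 35.90
    min: float = 3.0
    max: float = 622.0

    @model_validator(mode="after")
    def _check(self) -> "LengthModel":
        if self.sd < 0 or self.mean < 0:
            raise ValueError("episode_length: mean and sd must be non-negative")
        if self.min > self.max:
            raise ValueError("episode_length: min exceeds max")
        return self


class DisciplineModel(BaseModel):
    """Per-discipline use probability and conditional hours (log-normal)."""

    use_prob: float = Field(ge=0.0, le=1.0)
    mean_hours: float = Field(ge=0.0)
    sd_hours: float = Field(ge=0.0)


class UnpaidModel(BaseModel):
    """3-day unpaid-care self-report: log-normal admission/discharge pair."""

    mean_3day: float = Field(default=10.6, ge=0.0)
    sd_3day: float = Field(default=14.0, ge=0.0)
    correlation: float = Field(default=0.8, ge=-1.0, le=1.0)


def _default_disciplines() -> dict[str, DisciplineModel]:
    # Conditional means chosen so use_prob * mean_hours matches the documented
    # per-episode marginal means; SDs keep the documented right skew.
    params = {
        "RPN": (0.90, 15.5, 13.9),
        "RN": (0.90, 14.3, 15.1),
        "OT": (0.70, 6.6, 7.3),
        "PT": (0.80, 6.9, 6.7),
        "SLP": (0.15, 6.5, 8.5),
        "SW": (0.50, 7.2, 8.1),
        "RD": (0.40, 4.8, 5.2),
        "PTA": (0.70, 12.9, 11.4),
        "PSW": (0.95, 43.5, 55.2),
    }
    return {d: DisciplineModel(use_prob=p, mean_hours=m, sd_hours=s)
            for d, (p, m, s) in params.items()}


def _default_group_mix() -> dict[str, dict[str, float]]:
    """Within-category group shares from the reference cohort distribution.

    Structurally empty reference groups keep probability 0 except that a
    category whose reference total is 0 falls back to uniform.
    """
    mix: dict[str, dict[str, float]] = {}
    for cat in CATEGORY_ORDER:
        groups = CATEGORY_GROUPS[cat]
        total = sum(REFERENCE_GROUP_COUNTS_FULL[g] for g in groups)
        if total == 0:
            mix[cat] = {g: 1.0 / len(groups) for g in groups}
        else:
            mix[cat] = {g: REFERENCE_GROUP_COUNTS_FULL[g] / total for g in groups}
    return mix


class CohortConfig(BaseModel):
    """Full parameterization of a synthetic cohort."""

    n_episodes: int = Field(default=1680, ge=0)
    n_programs: int = Field(default=8, ge=1)
    episode_length: LengthModel = Field(default_factory=LengthModel)
    category_mix: tuple[float, ...] = REFERENCE_CATEGORY_MIX
    within_category_group_mix: dict[str, dict[str, float]] = Field(
        default_factory=_default_group_mix
    )
    discipline_hours: dict[str, DisciplineModel] = Field(default_factory=_default_disciplines)
    unpaid_3day: UnpaidModel = Field(default_factory=UnpaidModel)
    group_effect_multipliers: dict[str, float] = Field(
        default_factory=lambda: dict(REFERENCE_GROUP_EFFECTS)
    )
    unpaid_group_effect_multipliers: dict[str, float] = Field(
        default_factory=lambda: dict(REFERENCE_UNPAID_GROUP_EFFECTS)
    )
    program_effect_multipliers: Optional[list[float]] = None
    extra_trigger_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    missing_billing_rate: float = Field(default=0.255, ge=0.0, le=1.0)
    missing_discharge_rate: float = Field(default=0.20, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if len(self.category_mix) != len(CATEGORY_ORDER):
            raise ValueError("category_mix: must have one probability per category (7)")
        if any(p < 0 for p in self.category_mix):
            raise ValueError("category_mix: negative probability")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix: probabilities must sum to 1 within 1e-9")
        for cat in CATEGORY_ORDER:
            shares = self.within_category_group_mix.get(cat)
            if shares is None:
                raise ValueError(f"within_category_group_mix: missing category {cat}")
            if set(shares) != set(CATEGORY_GROUPS[cat]):
                raise ValueError(f"within_category_group_mix[{cat}]: must cover its groups exactly")
            if any(p < 0 for p in shares.values()):
                raise ValueError(f"within_category_group_mix[{cat}]: negative probability")
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ValueError(f"within_category_group_mix[{cat}]: must sum to 1 within 1e-9")
        if set(self.discipline_hours) != set(DISCIPLINES):
            raise ValueError("discipline_hours: must cover the nine disciplines exactly")
        for field_name, table in (
            ("group_effect_multipliers", self.group_effect_multipliers),
            ("unpaid_group_effect_multipliers", self.unpaid_group_effect_multipliers),
        ):
            missing = set(GROUP_ORDER) - set(table)
            if missing:
                raise ValueError(f"{field_name}: missing groups {sorted(missing)}")
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{field_name}: negative multiplier")
        if self.program_effect_multipliers is not None:
            if len(self.program_effect_multipliers) != self.n_programs:
                raise ValueError("program_effect_multipliers: one value per program required")
            if any(v < 0 for v in self.program_effect_multipliers):
                raise ValueError("program_effect_multipliers: negative multiplier")
        return self


def _validated(config: CohortConfig | dict) -> CohortConfig:
    try:
        if isinstance(config, CohortConfig):
            return CohortConfig.model_validate(config.model_dump())
        return CohortConfig.model_validate(config)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Log-normal samples with the given arithmetic mean and SD."""
    if mean <= 0:
        return np.zeros(size) if size else 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _sample_adl_in_band(rng: np.random.Generator, band: Optional[list[str]],
                        rules: RuleConfig) -> dict[str, int]:
    """ADL item codes whose banded score lands in one of the allowed bands."""
    scale = rules.adl_scale
    bands = band if band is not None else ["A", "B", "C", "D"]
    target_band = bands[int(rng.integers(len(bands)))]

    unit_weights = all(w == 1.0 for w in scale.weights.values())
    lo_score, hi_score = scale.min_score, scale.max_score
    bounds = {
        "A": (lo_score, scale.band_cutpoints["A"]),
        "B": (scale.band_cutpoints["A"] + 1, scale.band_cutpoints["B"]),
        "C": (scale.band_cutpoints["B"] + 1, scale.band_cutpoints["C"]),
        "D": (scale.band_cutpoints["C"] + 1, hi_score),
    }
    if unit_weights:
        # compose an integer item vector with the target sum
        s_lo, s_hi = bounds[target_band]
        s = int(rng.integers(int(max(s_lo, lo_score)), int(min(s_hi, hi_score)) + 1))
        codes: dict[str, int] = {}
        remaining, k = s, len(scale.items)
        for item in scale.items:
            k -= 1
            lo = max(scale.code_min, remaining - scale.code_max * k)
            hi = min(scale.code_max, remaining - scale.code_min * k)
            code = int(rng.integers(lo, hi + 1))
            codes[item] = code
            remaining -= code
        return codes
    # non-unit weights: rejection sampling against the banded weighted score
    for _ in range(1000):
        codes = {i: int(rng.integers(scale.code_min, scale.code_max + 1)) for i in scale.items}
        if scale.band(scale.score(codes)) == target_band:
            return codes
    raise ConfigurationError(
        f"adl_scale: could not sample an item vector in band {target_band}"
    )


def _sample_iadl(rng: np.random.Generator, requirement: str, rules: RuleConfig) -> dict[str, int]:
    scale = rules.iadl_scale
    cut = scale.difficulty_cutpoint
    if requirement == "any":
        requirement = "some" if rng.random() < 0.8 else "none"
    if requirement == "none":
        return {i: int(rng.integers(scale.code_min, cut)) for i in scale.items}
    codes = {i: int(rng.integers(scale.code_min, scale.code_max + 1)) for i in scale.items}
    if all(c < cut for c in codes.values()):
        forced = scale.items[int(rng.integers(len(scale.items)))]
        codes[forced] = int(rng.integers(cut, scale.code_max + 1))
    return codes


def _split_rule_for_group(rules: RuleConfig, category: str, group: str):
    for rule in rules.category(category).splits:
        if rule.group == group:
            return rule
    raise ConfigurationError(f"group {group} has no split rule in {category}")


def generate_cohort(
    config: CohortConfig | dict, rules: Optional[RuleConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (assessments, billing) tables for a synthetic cohort.

    Deterministic in (config, seed): the same config reproduces the same
    tables byte-for-byte. The ``sampled_group`` column records the generator's
    ground-truth group for each episode; the configured grouper re-derives it
    from the planted items (a mismatch would be a generator defect and raises).
    Missingness (billing, discharge reports) is applied before returning, per
    the config rates.
    """
    config = _validated(config)
    rules = rules or default_rules()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    behaviour_flags = rules.category("BehaviourProblems").trigger.behaviour_any or []
    clinical_lists = {
        cat: rules.category(cat).trigger.clinical_any or []
        for cat in ("ExtensiveServices", "SpecialCare", "ClinicallyComplex")
    }
    rehab_threshold = rules.category("Rehabilitation").trigger.therapy_minutes_min or 120.0
    cog_threshold = rules.category("ImpairedCognition").trigger.cognitive_performance_min or 3
    cat_rank = {name: i for i, name in enumerate(CATEGORY_ORDER)}
    program_mult = config.program_effect_multipliers or [1.0] * config.n_programs

    assess_rows: list[dict] = []
    billing_rows: list[dict] = []
    origin = date(2019, 1, 1)

    for i in range(config.n_episodes):
        episode_id = f"E{i + 1:05d}"
        program_idx = int(rng.integers(config.n_programs))
        category = CATEGORY_ORDER[rng.choice(len(CATEGORY_ORDER), p=np.asarray(config.category_mix))]
        shares = config.within_category_group_mix[category]
        groups = CATEGORY_GROUPS[category]
        group = groups[rng.choice(len(groups), p=np.asarray([shares[g] for g in groups]))]
        split = _split_rule_for_group(rules, category, group)

        # episode length and dates
        lm = config.episode_length
        if lm.sd > 0:
            a, b = (lm.min - lm.mean) / lm.sd, (lm.max - lm.mean) / lm.sd
            days = int(round(float(truncnorm.rvs(a, b, loc=lm.mean, scale=lm.sd, random_state=rng))))
        else:
            days = int(round(lm.mean))
        days = int(np.clip(days, max(lm.min, 1), lm.max))
        start = origin + timedelta(days=int(rng.integers(0, 1100)))
        end = start + timedelta(days=days)

        # plant the target category's trigger; clear higher-priority ones
        clinical: set[str] = set()
        behaviour: set[str] = set()
        therapy = float(rng.uniform(0.0, rehab_threshold * 0.95))
        cognition = int(rng.integers(0, cog_threshold))
        if category == "Rehabilitation":
            therapy = float(rng.uniform(rehab_threshold, rehab_threshold + 240.0))
        elif category == "ExtensiveServices":
            pool = clinical_lists["ExtensiveServices"]
            k = min(split.services_min or 1, len(pool))
            clinical.update(rng.choice(pool, size=k, replace=False))
        elif category == "SpecialCare":
            clinical.add(str(rng.choice(clinical_lists["SpecialCare"])))
        elif category == "ClinicallyComplex":
            clinical.add(str(rng.choice(clinical_lists["ClinicallyComplex"])))
        elif category == "ImpairedCognition":
            cognition = int(rng.integers(cog_threshold, cog_threshold + 4))
        elif category == "BehaviourProblems":
            behaviour.add(str(rng.choice(behaviour_flags)))

        # sprinkle lower-priority triggers for realism (hierarchy makes them inert)
        for extra, rank in (("SpecialCare", 2), ("ClinicallyComplex", 3),
                            ("ImpairedCognition", 4), ("BehaviourProblems", 5)):
            if rank > cat_rank[category] and rng.random() < config.extra_trigger_rate:
                if extra == "ImpairedCognition":
                    cognition = int(rng.integers(cog_threshold, cog_threshold + 4))
                elif extra == "BehaviourProblems":
                    behaviour.add(str(rng.choice(behaviour_flags)))
                else:
                    clinical.add(str(rng.choice(clinical_lists[extra])))

        adl = _sample_adl_in_band(rng, split.adl_bands, rules)
        iadl = _sample_iadl(rng, split.iadl, rules)

        # unpaid 3-day self-reports: correlated log-normal pair scaled by the
        # group's unpaid-care effect (its own profile, distinct from paid care)
        g_mult = config.group_effect_multipliers[group]
        gu_mult = config.unpaid_group_effect_multipliers[group]
        p_mult = program_mult[program_idx]
        um = config.unpaid_3day
        mean_unpaid = um.mean_3day * gu_mult
        if mean_unpaid > 0 and um.sd_3day > 0:
            sigma2 = np.log1p((um.sd_3day * gu_mult / mean_unpaid) ** 2)
            mu = np.log(mean_unpaid) - sigma2 / 2.0
            z1 = rng.standard_normal()
            z2 = um.correlation * z1 + np.sqrt(max(0.0, 1 - um.correlation**2)) * rng.standard_normal()
            unpaid_adm = float(np.exp(mu + np.sqrt(sigma2) * z1))
            unpaid_dis = float(np.exp(mu + np.sqrt(sigma2) * z2))
        else:
            unpaid_adm = unpaid_dis = float(mean_unpaid)

        age = float(np.clip(rng.normal(76.4, 12.9), 17, 110))
        sex = "F" if rng.random() < 0.5925 else "M"

        row = {
            "episode_id": episode_id,
            "client_id": f"C{i + 1:05d}",
            "program_id": f"P{program_idx + 1}",
            "episode_start": start.isoformat(),
            "episode_end": end.isoformat(),
            "episode_days": days,
            "cognitive_performance": cognition,
            "behaviour_flags": join_flags(behaviour),
            "clinical_flags": join_flags(clinical),
            "therapy_minutes_7day": round(therapy, 1),
            "unpaid_hours_3day_admission": round(unpaid_adm, 2),
            "unpaid_hours_3day_discharge": round(unpaid_dis, 2),
            "age": round(age, 1),
            "sex": sex,
            "sampled_group": group,
        }
        for item, code in adl.items():
            row[f"adl_{item}"] = code
        for item, code in iadl.items():
            row[f"iadl_{item}"] = code
        assess_rows.append(row)

        # paid hours by discipline, scaled by group/program effects and length
        length_scale = days / lm.mean if lm.mean > 0 else 1.0
        for disc in DISCIPLINES:
            dm = config.discipline_hours[disc]
            if rng.random() < dm.use_prob:
                scale = g_mult * p_mult * length_scale
                hours = float(_lognormal(rng, dm.mean_hours * scale, dm.sd_hours * scale))
                billing_rows.append(
                    {"episode_id": episode_id, "discipline": disc, "hours": round(hours, 2)}
                )

    # stable column order: ids, dates, items, then the remaining fixed columns
    ordered = ["episode_id", "client_id", "program_id", "episode_start", "episode_end",
               "episode_days"] + [f"adl_{i}" for i in rules.adl_scale.items] + [
        f"iadl_{i}" for i in rules.iadl_scale.items] + [
        "cognitive_performance", "behaviour_flags", "clinical_flags",
        "therapy_minutes_7day", "unpaid_hours_3day_admission",
        "unpaid_hours_3day_discharge", "age", "sex", "sampled_group"]
    assessments = pd.DataFrame(assess_rows, columns=ordered)
    billing = pd.DataFrame(billing_rows, columns=["episode_id", "discipline", "hours"])

    _self_check(assessments, rules)
    return inject_missingness(assessments, billing, config)


def _self_check(assessments: pd.DataFrame, rules: RuleConfig) -> None:
    """The configured grouper must reproduce every sampled target group."""
    from .grouper import classify_episode  # local import avoids a cycle

    for row in assessments.to_dict("records"):
        got = classify_episode(record_from_row(row, rules), rules).code
        if got != row["sampled_group"]:
            raise RuntimeError(
                f"generator defect: episode {row['episode_id']} sampled "
                f"{row['sampled_group']} but classifies as {got}"
            )


def inject_missingness(
    assessments: pd.DataFrame, billing: pd.DataFrame, config: CohortConfig | dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove billing records and discharge unpaid reports for seeded random fractions.

    Each episode independently loses its billing records with probability
    ``missing_billing_rate`` and its discharge self-report with probability
    ``missing_discharge_rate``; admission data are never removed. Seeded from
    ``config.seed`` (its own stream), so the removed sets are reproducible.
    """
    config = _validated(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    assessments = assessments.copy()
    episode_ids = assessments["episode_id"].tolist()

    drop_billing = {
        eid for eid in episode_ids if rng.random() < config.missing_billing_rate
    }
    drop_discharge = {
        eid for eid in episode_ids if rng.random() < config.missing_discharge_rate
    }
    if len(billing):
        billing = billing[~billing["episode_id"].isin(drop_billing)].reset_index(drop=True)
    if drop_discharge:
        mask = assessments["episode_id"].isin(drop_discharge)
        assessments.loc[mask, "unpaid_hours_3day_discharge"] = np.nan
    return assessments, billing
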