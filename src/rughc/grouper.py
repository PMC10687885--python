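"""Hierarchical RUG-III/HC classification.

Each care episode is assigned to exactly one of the 23 groups: category
triggers are evaluated in hierarchy order (rank 1 first) and the first
satisfied trigger fixes the clinical category; the category's split map then
fixes the group from the ADL band, the IADL difficulty band and, for
Extensive services, the count of distinct extensive services. Reduced
physical functions is the always-true terminal category, so classification is
total over valid records.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .errors import ClassificationError, ConfigurationError
from .records import AssessmentRecord, record_from_row
from .rules import RuleConfig
from .taxonomy import CATEGORY_GROUPS, CATEGORY_ORDER, GROUPS, RugGroup

__all__ = [
    "adl_score",
    "iadl_band",
    "classify_episode",
    "classify_frame",
    "distribution_table",
]


def adl_score(record: AssessmentRecord, rules: RuleConfig) -> tuple[float, str]:
    """Weighted ADL dependency score and its band (A = lowest limitation .. D).

    Monotone by construction: item weights are non-negative, so increasing
    any item code never lowers the band.
    """
    scale = rules.adl_scale
    for item in scale.items:
        if item not in record.adl_items:
            raise ClassificationError(f"missing ADL item {item!r}")
        code = record.adl_items[item]
        if not scale.code_min <= code <= scale.code_max:
            raise ClassificationError(f"ADL item {item!r} code {code} outside configured range")
    score = scale.score(record.adl_items)
    return score, scale.band(score)


def iadl_band(record: AssessmentRecord, rules: RuleConfig) -> str:
    """'none' iff every IADL item codes below the difficulty cut-point, else 'some'."""
    scale = rules.iadl_scale
    for item in scale.items:
        if item not in record.iadl_items:
            raise ClassificationError(f"missing IADL item {item!r}")
        code = record.iadl_items[item]
        if not scale.code_min <= code <= scale.code_max:
            raise ClassificationError(f"IADL item {item!r} code {code} outside configured range")
    some = any(record.iadl_items[item] >= scale.difficulty_cutpoint for item in scale.items)
    return "some" if some else "none"


def _trigger_satisfied(record: AssessmentRecord, trigger) -> bool:
    if trigger.always:
        return True
    if (
        trigger.therapy_minutes_min is not None
        and record.therapy_minutes_7day >= trigger.therapy_minutes_min
    ):
        return True
    if trigger.clinical_any and record.clinical_flags.intersection(trigger.clinical_any):
        return True
    if trigger.behaviour_any and record.behaviour_flags.intersection(trigger.behaviour_any):
        return True
    if (
        trigger.cognitive_performance_min is not None
        and record.cognitive_performance >= trigger.cognitive_performance_min
    ):
        return True
    return False


def classify_episode(record: AssessmentRecord, rules: RuleConfig) -> RugGroup:
    """Classify one episode into its RUG-III/HC group."""
    _, band = adl_score(record, rules)
    iadl = iadl_band(record, rules)
    n_services = len(record.clinical_flags.intersection(rules.extensive_services))

    for category in rules.categories:
        if not _trigger_satisfied(record, category.trigger):
            continue
        for rule in category.splits:
            if rule.matches(band, iadl, n_services):
                return GROUPS[rule.group]
        raise ConfigurationError(
            f"split map of {category.name} has no rule for ADL band {band}, "
            f"IADL {iadl}, services {n_services}"
        )
    raise ConfigurationError("no category triggered; terminal category misconfigured")


def classify_frame(assessments: pd.DataFrame, rules: RuleConfig) -> pd.Series:
    """Classify every row of an assessment table.

    Returns a Series of group codes indexed by ``episode_id``.
    """
    codes = {}
    for row in assessments.to_dict("records"):
        record = record_from_row(row, rules)
        codes[record.episode_id] = classify_episode(record, rules).code
    return pd.Series(codes, name="group", dtype="object").rename_axis("episode_id")


def distribution_table(groups: Iterable[str] | Mapping[str, int]) -> pd.DataFrame:
    """Count and percentage of episodes per group and category.

    ``groups`` is either an iterable of group codes (one per episode) or a
    mapping of group code to count. Category rows aggregate their groups and a
    final ``Total`` row closes the table; percentages are 100*count/total
    rounded to one decimal.
    """
    if isinstance(groups, Mapping):
        counts = {code: int(n) for code, n in groups.items()}
    else:
        counts = pd.Series(list(groups), dtype="object").value_counts().to_dict()
    unknown = set(counts) - set(GROUPS)
    if unknown:
        raise ClassificationError(f"unknown group codes in distribution input: {sorted(unknown)}")

    total = sum(counts.values())

    def pct(n: int) -> float:
        return round(100.0 * n / total, 1) if total else 0.0

    rows = []
    for cat in CATEGORY_ORDER:
        cat_groups = CATEGORY_GROUPS[cat]
        cat_n = sum(counts.get(g, 0) for g in cat_groups)
        rows.append({"label": cat, "level": "category", "category": cat,
                     "count": cat_n, "percentage": pct(cat_n)})
        for g in cat_groups:
            rows.append({"label": g, "level": "group", "category": cat,
                         "count": counts.get(g, 0), "percentage": pct(counts.get(g, 0))})
    rows.append({"label": "Total", "level": "total", "category": "",
                 "count": total, "percentage": 100.0 if total else 0.0})
    return pd.DataFrame(rows)
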