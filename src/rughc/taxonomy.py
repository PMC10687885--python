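"""The RUG-III/HC taxonomy: 7 clinical categories and their 23 groups.

The Resource Utilization Groups system for Home Care (RUG-III/HC) is a
hierarchical case-mix classification. Seven clinical categories are evaluated
in a fixed priority order (Rehabilitation first, Reduced physical functions as
the terminal catch-all); within the category, functional dependency splits the
episode into one of the category's groups. The category/group structure is
fixed by the system; the clinical triggers and split thresholds live in the
editable rule configuration (:mod:`rughc.rules`).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RugCategory",
    "RugGroup",
    "CATEGORY_ORDER",
    "CATEGORY_GROUPS",
    "CATEGORIES",
    "GROUPS",
    "GROUP_ORDER",
    "GROUP_CATEGORY",
    "DISCIPLINES",
    "MEASURES",
    "MEASURE_LABELS",
    "ADL_BANDS",
]


@dataclass(frozen=True)
class RugCategory:
    """One of the seven clinical categories, with its hierarchy rank (1 = highest priority)."""

    name: str
    rank: int


@dataclass(frozen=True)
class RugGroup:
    """One of the 23 groups; within-category rank 1 = highest expected resource use."""

    code: str
    category: RugCategory
    within_category_rank: int


#: Evaluation order of the hierarchy (rank 1 first). Reduced physical
#: functions is the always-true terminal category.
CATEGORY_ORDER: tuple[str, ...] = (
    "Rehabilitation",
    "ExtensiveServices",
    "SpecialCare",
    "ClinicallyComplex",
    "ImpairedCognition",
    "BehaviourProblems",
    "ReducedPhysicalFunctions",
)

#: Group codes per category, ordered by decreasing expected resource use.
CATEGORY_GROUPS: dict[str, tuple[str, ...]] = {
    "Rehabilitation": ("RB", "RA2", "RA1"),
    "ExtensiveServices": ("SE3", "SE2", "SE1"),
    "SpecialCare": ("SSB", "SSA"),
    "ClinicallyComplex": ("CC", "CB", "CA2", "CA1"),
    "ImpairedCognition": ("IB", "IA2", "IA1"),
    "BehaviourProblems": ("BB", "BA2", "BA1"),
    "ReducedPhysicalFunctions": ("PD", "PC", "PB", "PA2", "PA1"),
}

CATEGORIES: dict[str, RugCategory] = {
    name: RugCategory(name=name, rank=i + 1) for i, name in enumerate(CATEGORY_ORDER)
}

GROUPS: dict[str, RugGroup] = {
    code: RugGroup(code=code, category=CATEGORIES[cat], within_category_rank=j + 1)
    for cat in CATEGORY_ORDER
    for j, code in enumerate(CATEGORY_GROUPS[cat])
}

GROUP_ORDER: tuple[str, ...] = tuple(
    code for cat in CATEGORY_ORDER for code in CATEGORY_GROUPS[cat]
)

GROUP_CATEGORY: dict[str, str] = {g: GROUPS[g].category.name for g in GROUP_ORDER}

#: The nine provider disciplines appearing in home-care billing records.
DISCIPLINES: tuple[str, ...] = ("RPN", "RN", "OT", "PT", "SLP", "SW", "RD", "PTA", "PSW")

#: The four per-episode resource-utilization measures.
MEASURES: tuple[str, ...] = ("paid_hours", "paid_cost", "total_hours", "total_cost")

MEASURE_LABELS: dict[str, str] = {
    "paid_hours": "Paid care time",
    "paid_cost": "Paid care cost",
    "total_hours": "Paid + unpaid care time",
    "total_cost": "Paid + unpaid care cost",
}

ADL_BANDS: tuple[str, ...] = ("A", "B", "C", "D")
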