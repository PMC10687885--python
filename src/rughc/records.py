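"""Episode-level record types and their tabular (DataFrame row) encoding.

Assessments and billing move through the pipeline as pandas DataFrames (one
row per episode / per episode-discipline); these dataclasses are the typed
view a single row converts to for classification. ADL and IADL items are
stored in columns named ``adl_<item>`` / ``iadl_<item>``; flag sets are
semicolon-joined strings in the ``clinical_flags`` / ``behaviour_flags``
columns (empty string = no flags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

from .errors import ClassificationError
from .rules import RuleConfig

__all__ = ["AssessmentRecord", "BillingRecord", "record_from_row", "split_flags", "join_flags"]


@dataclass
class AssessmentRecord:
    """One care episode's admission assessment (plus optional discharge items)."""

    episode_id: str
    client_id: str
    program_id: str
    episode_days: int
    adl_items: dict[str, int]
    iadl_items: dict[str, int]
    cognitive_performance: int
    behaviour_flags: set[str] = field(default_factory=set)
    clinical_flags: set[str] = field(default_factory=set)
    therapy_minutes_7day: float = 0.0
    unpaid_hours_3day_admission: float = 0.0
    unpaid_hours_3day_discharge: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[str] = None


@dataclass
class BillingRecord:
    """Hours of paid care for one episode by one provider discipline."""

    episode_id: str
    discipline: str
    hours: float


def split_flags(value: Any) -> set[str]:
    """Decode a semicolon-joined flag string (NaN/empty -> empty set)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return set()
    text = str(value).strip()
    return {tok for tok in text.split(";") if tok} if text else set()


def join_flags(flags: set[str]) -> str:
    return ";".join(sorted(flags))


def record_from_row(row: Mapping[str, Any], rules: RuleConfig) -> AssessmentRecord:
    """Build a typed record from an assessment-table row.

    Raises :class:`ClassificationError` naming the first missing or invalid
    item, mirroring the analysis convention of excluding rather than imputing
    incomplete assessments.
    """

    def item(prefix: str, name: str, lo: int, hi: int) -> int:
        col = f"{prefix}_{name}"
        value = row.get(col)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ClassificationError(f"missing {prefix.upper()} item {name!r} (column {col})")
        code = int(value)
        if code != value or not lo <= code <= hi:
            raise ClassificationError(
                f"invalid {prefix.upper()} code {value!r} for item {name!r} "
                f"(expected integer in [{lo}, {hi}])"
            )
        return code

    adl = {
        name: item("adl", name, rules.adl_scale.code_min, rules.adl_scale.code_max)
        for name in rules.adl_scale.items
    }
    iadl = {
        name: item("iadl", name, rules.iadl_scale.code_min, rules.iadl_scale.code_max)
        for name in rules.iadl_scale.items
    }

    cognition = row.get("cognitive_performance")
    if cognition is None or (isinstance(cognition, float) and math.isnan(cognition)):
        raise ClassificationError("missing cognitive_performance score")
    if cognition < 0:
        raise ClassificationError(f"negative cognitive_performance score {cognition!r}")

    discharge = row.get("unpaid_hours_3day_discharge")
    if discharge is not None and isinstance(discharge, float) and math.isnan(discharge):
        discharge = None

    return AssessmentRecord(
        episode_id=str(row.get("episode_id", "")),
        client_id=str(row.get("client_id", "")),
        program_id=str(row.get("program_id", "")),
        episode_days=int(row.get("episode_days", 1)),
        adl_items=adl,
        iadl_items=iadl,
        cognitive_performance=int(cognition),
        behaviour_flags=split_flags(row.get("behaviour_flags")),
        clinical_flags=split_flags(row.get("clinical_flags")),
        therapy_minutes_7day=float(row.get("therapy_minutes_7day", 0.0) or 0.0),
        unpaid_hours_3day_admission=float(row.get("unpaid_hours_3day_admission", 0.0) or 0.0),
        unpaid_hours_3day_discharge=None if discharge is None else float(discharge),
        age=row.get("age"),
        sex=row.get("sex"),
    )
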