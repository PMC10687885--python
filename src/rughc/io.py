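"""Reading and writing cohort tables (comma-separated, UTF-8, header row).

Schema
------
Assessments: one row per episode with columns ``episode_id``, ``client_id``,
``program_id``, ``episode_start``/``episode_end`` (ISO-8601), ``episode_days``,
``adl_<item>`` and ``iadl_<item>`` ordinal codes, ``cognitive_performance``,
``behaviour_flags``/``clinical_flags`` (semicolon-joined), ``therapy_minutes_7day``,
``unpaid_hours_3day_admission``, ``unpaid_hours_3day_discharge`` (may be empty),
``age``, ``sex``. Unknown columns are ignored with a warning.

Billing: one row per episode-discipline with ``episode_id``, ``discipline``
(one of the nine-discipline vocabulary) and non-negative ``hours``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError
from .rules import RuleConfig, default_rules
from .taxonomy import DISCIPLINES

__all__ = ["CohortReadResult", "read_cohort", "write_cohort"]

log = logging.getLogger("rughc.io")

MANDATORY_ASSESSMENT = [
    "episode_id", "program_id", "episode_days", "cognitive_performance",
    "unpaid_hours_3day_admission",
]
MANDATORY_BILLING = ["episode_id", "discipline", "hours"]


@dataclass
class CohortReadResult:
    """Validated tables plus the row-level failures collected on the way."""

    assessments: pd.DataFrame
    billing: pd.DataFrame
    row_errors: list[str] = field(default_factory=list)


def write_cohort(assessments: pd.DataFrame, billing: pd.DataFrame, outdir: str) -> dict[str, str]:
    """Write the two cohort tables as CSV; returns the written paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "assessments": os.path.join(outdir, "assessments.csv"),
        "billing": os.path.join(outdir, "billing.csv"),
    }
    assessments.to_csv(paths["assessments"], index=False)
    billing.to_csv(paths["billing"], index=False)
    return paths


def _validate_assessments(df: pd.DataFrame, rules: RuleConfig) -> tuple[pd.DataFrame, list[str]]:
    errors: list[str] = []
    item_cols = [f"adl_{i}" for i in rules.adl_scale.items] + [
        f"iadl_{i}" for i in rules.iadl_scale.items
    ]
    missing = [c for c in MANDATORY_ASSESSMENT + item_cols if c not in df.columns]
    if missing:
        raise DataError(f"assessment file lacks mandatory column(s): {missing}")

    keep_rows = []
    for idx, row in enumerate(df.to_dict("records")):
        problems = []
        if not row["episode_id"]:
            problems.append("empty episode_id")
        try:
            days = int(row["episode_days"])
            if days < 1:
                problems.append(f"episode_days {days} < 1")
        except (TypeError, ValueError):
            problems.append(f"non-integer episode_days {row['episode_days']!r}")
        for scale, prefix, lo, hi in (
            (rules.adl_scale, "adl", rules.adl_scale.code_min, rules.adl_scale.code_max),
            (rules.iadl_scale, "iadl", rules.iadl_scale.code_min, rules.iadl_scale.code_max),
        ):
            for item in scale.items:
                val = row[f"{prefix}_{item}"]
                try:
                    code = int(val)
                    if not lo <= code <= hi:
                        problems.append(f"{prefix}_{item}={code} outside [{lo},{hi}]")
                except (TypeError, ValueError):
                    problems.append(f"{prefix}_{item}={val!r} not an integer code")
        adm = row["unpaid_hours_3day_admission"]
        try:
            if float(adm) < 0:
                problems.append(f"negative unpaid admission report {adm!r}")
        except (TypeError, ValueError):
            problems.append(f"non-numeric unpaid admission report {adm!r}")
        if ("episode_start" in df.columns and "episode_end" in df.columns
                and pd.notna(row.get("episode_start")) and pd.notna(row.get("episode_end"))
                and str(row["episode_end"]) < str(row["episode_start"])):
            problems.append("episode_end precedes episode_start")
        if problems:
            errors.append(f"assessments row {idx}: " + "; ".join(problems))
        else:
            keep_rows.append(idx)
    return df.iloc[keep_rows].reset_index(drop=True), errors


def _validate_billing(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    errors: list[str] = []
    missing = [c for c in MANDATORY_BILLING if c not in df.columns]
    if missing:
        raise DataError(f"billing file lacks mandatory column(s): {missing}")
    keep_rows = []
    for idx, row in enumerate(df.to_dict("records")):
        problems = []
        if row["discipline"] not in DISCIPLINES:
            problems.append(f"unknown discipline {row['discipline']!r}")
        try:
            if float(row["hours"]) < 0:
                problems.append(f"negative hours {row['hours']!r}")
        except (TypeError, ValueError):
            problems.append(f"non-numeric hours {row['hours']!r}")
        if problems:
            errors.append(f"billing row {idx}: " + "; ".join(problems))
        else:
            keep_rows.append(idx)
    return df.iloc[keep_rows].reset_index(drop=True), errors


def read_cohort(
    assessments_path: str,
    billing_path: str,
    rules: RuleConfig | None = None,
) -> CohortReadResult:
    """Read and validate cohort CSVs; row failures are collected, not fatal."""
    rules = rules or default_rules()
    assessments = pd.read_csv(assessments_path, dtype={"episode_id": str, "program_id": str,
                                                       "client_id": str})
    billing = pd.read_csv(billing_path, dtype={"episode_id": str, "discipline": str})

    known = set(MANDATORY_ASSESSMENT) | {
        "client_id", "episode_start", "episode_end", "behaviour_flags", "clinical_flags",
        "therapy_minutes_7day", "unpaid_hours_3day_discharge", "age", "sex", "sampled_group",
    } | {f"adl_{i}" for i in rules.adl_scale.items} | {f"iadl_{i}" for i in rules.iadl_scale.items}
    unknown = [c for c in assessments.columns if c not in known]
    if unknown:
        log.warning("ignoring unknown assessment column(s): %s", unknown)

    assessments, a_errors = _validate_assessments(assessments, rules)
    billing, b_errors = _validate_billing(billing)
    errors = a_errors + b_errors
    if errors:
        log.warning("read_cohort: %d row(s) failed validation", len(errors))
    return CohortReadResult(assessments=assessments, billing=billing, row_errors=errors)
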