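"""Per-episode resource utilization and the operational-sample trimming rule.

Paid care is costed with standardized weights: each discipline's hourly
billing rate divided by the PSW rate, so the PSW weight is exactly 1 and all
costs are expressed in PSW-hour equivalents (currency cancels). Unpaid care
is estimated from the 3-day self-reports at admission and discharge
(averaged, divided by 3 to a daily rate, multiplied by episode length) and
valued at the PSW replacement rate (weight 1.0 by default).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigurationError, DataError

__all__ = [
    "CostWeightTable",
    "standardize_weights",
    "paid_measures",
    "estimate_unpaid_hours",
    "episode_measures",
    "trim_operational",
]


class CostWeightTable(BaseModel):
    """Hourly rates and the PSW-standardized weights derived from them."""

    hourly_rate: dict[str, float]
    weight: dict[str, float]
    unpaid_weight: float = Field(default=1.0, gt=0.0)


def standardize_weights(
    rates: dict[str, float], unpaid_weight: float = 1.0
) -> CostWeightTable:
    """Divide every hourly rate by the PSW rate; weight['PSW'] is exactly 1.0.

    Weights are invariant to rescaling all rates by a common factor.
    """
    if "PSW" not in rates:
        raise ConfigurationError("hourly rates must include the PSW reference discipline")
    for disc, rate in rates.items():
        if not rate > 0:
            raise ConfigurationError(f"hourly rate for {disc!r} must be positive, got {rate!r}")
    psw = rates["PSW"]
    weight = {disc: rate / psw for disc, rate in rates.items()}
    weight["PSW"] = 1.0
    try:
        return CostWeightTable(hourly_rate=dict(rates), weight=weight, unpaid_weight=unpaid_weight)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def paid_measures(billing: pd.DataFrame, weights: CostWeightTable) -> tuple[float, float]:
    """(paid_hours, paid_cost) for one episode's billing records.

    paid_hours is the plain sum of hours; paid_cost weights each discipline's
    hours by its standardized cost weight. Empty input yields (0.0, 0.0).
    """
    if len(billing) == 0:
        return 0.0, 0.0
    unknown = set(billing["discipline"]) - set(weights.weight)
    if unknown:
        raise DataError(f"unknown discipline(s) in billing records: {sorted(unknown)}")
    if (billing["hours"] < 0).any():
        raise DataError("negative hours in billing records")
    hours = float(billing["hours"].sum())
    cost = float((billing["hours"] * billing["discipline"].map(weights.weight)).sum())
    return hours, cost


def estimate_unpaid_hours(
    adm_3day: float, dis_3day: Optional[float], episode_days: int
) -> float:
    """Total unpaid hours over the episode from the 3-day self-reports.

    Daily rate = mean(admission, discharge) / 3, falling back to the admission
    report alone when the discharge assessment is missing; total = daily rate
    x episode length in days.
    """
    if episode_days < 1:
        raise DataError(f"episode_days must be >= 1, got {episode_days}")
    if adm_3day < 0 or (dis_3day is not None and dis_3day < 0):
        raise DataError("unpaid 3-day reports must be non-negative")
    if dis_3day is None or (isinstance(dis_3day, float) and math.isnan(dis_3day)):
        three_day = adm_3day
    else:
        three_day = (adm_3day + dis_3day) / 2.0
    return three_day / 3.0 * episode_days


def episode_measures(
    assessments: pd.DataFrame,
    billing: pd.DataFrame,
    weights: CostWeightTable,
) -> tuple[pd.DataFrame, int]:
    """Per-episode utilization table for all billing-complete episodes.

    Episodes without any billing record are excluded from cost computation
    (they remain classifiable upstream); the second return value is their
    count. Columns: episode_id, program_id, episode_days, paid_hours,
    paid_cost, unpaid_hours, total_hours, total_cost.
    """
    unknown = set(billing["discipline"]) - set(weights.weight) if len(billing) else set()
    if unknown:
        raise DataError(f"unknown discipline(s) in billing records: {sorted(unknown)}")
    if len(billing) and (billing["hours"] < 0).any():
        raise DataError("negative hours in billing records")

    billed_ids = set(billing["episode_id"]) if len(billing) else set()
    n_missing = int((~assessments["episode_id"].isin(billed_ids)).sum())

    if len(billing):
        w = billing["discipline"].map(weights.weight)
        paid = (
            billing.assign(weighted=billing["hours"] * w)
            .groupby("episode_id")[["hours", "weighted"]]
            .sum()
            .rename(columns={"hours": "paid_hours", "weighted": "paid_cost"})
        )
    else:
        paid = pd.DataFrame(columns=["paid_hours", "paid_cost"])

    keep = assessments[assessments["episode_id"].isin(billed_ids)].copy()
    rows = []
    for row in keep.to_dict("records"):
        unpaid = estimate_unpaid_hours(
            float(row["unpaid_hours_3day_admission"]),
            row.get("unpaid_hours_3day_discharge"),
            int(row["episode_days"]),
        )
        ph = float(paid.loc[row["episode_id"], "paid_hours"])
        pc = float(paid.loc[row["episode_id"], "paid_cost"])
        rows.append(
            {
                "episode_id": row["episode_id"],
                "program_id": row.get("program_id", ""),
                "episode_days": int(row["episode_days"]),
                "paid_hours": ph,
                "paid_cost": pc,
                "unpaid_hours": unpaid,
                "total_hours": ph + unpaid,
                "total_cost": pc + weights.unpaid_weight * unpaid,
            }
        )
    measures = pd.DataFrame(
        rows,
        columns=[
            "episode_id", "program_id", "episode_days", "paid_hours", "paid_cost",
            "unpaid_hours", "total_hours", "total_cost",
        ],
    )
    return measures, n_missing


def trim_operational(
    episodes: pd.DataFrame,
    low_pct: float = 0.01,
    high_pct: float = 0.05,
    days_col: str = "episode_days",
    method: str = "linear",
) -> pd.DataFrame:
    """Drop length-of-stay outliers: strictly below the ``low_pct`` quantile or
    strictly above the ``1 - high_pct`` quantile of episode length.

    Quantiles use numpy's inclusive linear interpolation by default; the
    convention is exposed via ``method`` because published sample sizes do not
    pin it down. With ``low_pct = high_pct = 0`` the input is returned
    unchanged; identical lengths are never trimmed (no strict outliers).
    """
    if low_pct < 0 or high_pct < 0:
        raise ConfigurationError("trim fractions must be non-negative")
    if low_pct + high_pct >= 1:
        raise ConfigurationError("trim fractions must sum to less than 1")
    if len(episodes) == 0:
        return episodes
    days = episodes[days_col].to_numpy(dtype=float)
    lo = np.quantile(days, low_pct, method=method)
    hi = np.quantile(days, 1.0 - high_pct, method=method)
    mask = (days >= lo) & (days <= hi)
    return episodes[mask]


def load_rates(path: str) -> dict[str, float]:
    """Read an hourly-rate table from YAML ({discipline: rate})."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("rate file must map disciplines to hourly rates")
    return {str(k): float(v) for k, v in raw.items()}


def default_weights(unpaid_weight: float = 1.0) -> CostWeightTable:
    """Standardized weights from the package's synthetic default rate card."""
    from .reference import DEFAULT_HOURLY_RATES

    return standardize_weights(DEFAULT_HOURLY_RATES, unpaid_weight)
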