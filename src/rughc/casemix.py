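"""Per-group case-mix indices and coefficients of variation.

For each of the four utilization measures (paid time, paid cost, paid+unpaid
time, paid+unpaid cost) and each of the 23 groups: n, mean, SD, the case-mix
index CMI = group mean / overall mean, and the coefficient of variation
CV = SD / mean. The overall row has CMI 1.00 by construction; the n-weighted
mean of group CMIs is exactly 1 for every measure. Groups with no episodes
report NA; groups with fewer than 10 episodes carry an instability flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .taxonomy import GROUP_ORDER, MEASURES

__all__ = ["cv", "CaseMixTable", "case_mix_table", "UNSTABLE_N"]

#: Groups with fewer episodes than this are flagged as unstable.
UNSTABLE_N = 10


def cv(values, ddof: int = 1) -> float:
    """Coefficient of variation: sample SD / mean of non-negative values.

    All-zero input returns 0.0 by convention; a single value has SD 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DataError("cv requires at least one value")
    if (arr < 0).any():
        raise DataError("cv is defined here for non-negative values only")
    mean = float(arr.mean())
    if mean == 0.0:
        return 0.0
    sd = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    return sd / mean


@dataclass
class CaseMixTable:
    """Per-group statistics for one sample; ``data`` is indexed by group code + 'Overall'."""

    data: pd.DataFrame
    sample_label: str
    n_total: int

    def cmi(self, group: str, measure: str) -> float:
        return float(self.data.loc[group, f"cmi_{measure}"])

    def formatted(self, decimals: int = 2) -> pd.DataFrame:
        """Display table with 'CMI (CV)' strings and literal NA for empty groups."""
        out = pd.DataFrame(index=self.data.index)
        out["n"] = self.data["n"]
        for m in MEASURES:
            cmi_col, cv_col = self.data[f"cmi_{m}"], self.data[f"cv_{m}"]
            out[m] = [
                "NA" if np.isnan(c) else f"{c:.{decimals}f} ({v:.{decimals}f})"
                for c, v in zip(cmi_col, cv_col)
            ]
        return out


def case_mix_table(
    episode_table: pd.DataFrame, sample_label: str = "full", ddof: int = 1
) -> CaseMixTable:
    """Build the per-group case-mix table from an episode-level table.

    ``episode_table`` needs a ``group`` column plus the four measure columns.
    SD is the sample SD (``ddof=1``) by default, 0 by convention for
    single-episode groups; empty groups report NaN (rendered NA). The overall
    row's CMIs equal 1 by construction.
    """
    if len(episode_table) == 0:
        raise DataError("case_mix_table requires at least one episode")
    missing = [c for c in ("group", *MEASURES) if c not in episode_table.columns]
    if missing:
        raise DataError(f"episode table lacks required column(s): {missing}")

    overall_means = {m: float(episode_table[m].mean()) for m in MEASURES}
    rows = []
    for code in GROUP_ORDER:
        sub = episode_table[episode_table["group"] == code]
        n = len(sub)
        row: dict = {"group": code, "n": n, "unstable": bool(0 < n < UNSTABLE_N)}
        for m in MEASURES:
            if n == 0:
                row.update({f"mean_{m}": np.nan, f"sd_{m}": np.nan,
                            f"cmi_{m}": np.nan, f"cv_{m}": np.nan})
                continue
            vals = sub[m].to_numpy(dtype=float)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=ddof)) if n > ddof else 0.0
            row[f"mean_{m}"] = mean
            row[f"sd_{m}"] = sd
            row[f"cmi_{m}"] = mean / overall_means[m] if overall_means[m] > 0 else np.nan
            row[f"cv_{m}"] = sd / mean if mean > 0 else 0.0
        rows.append(row)

    overall: dict = {"group": "Overall", "n": len(episode_table), "unstable": False}
    for m in MEASURES:
        vals = episode_table[m].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0
        overall[f"mean_{m}"] = mean
        overall[f"sd_{m}"] = sd
        overall[f"cmi_{m}"] = mean / mean if mean > 0 else np.nan
        overall[f"cv_{m}"] = sd / mean if mean > 0 else 0.0
    rows.append(overall)

    data = pd.DataFrame(rows).set_index("group")
    return CaseMixTable(data=data, sample_label=sample_label, n_total=len(episode_table))
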