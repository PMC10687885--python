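"""Variance in resource utilization explained by the case-mix system.

Each episode's utilization measure is regressed on the CMI of its group for
that measure (ordinary least squares with intercept), optionally adding a
program indicator encoded as dummies with the largest program as reference.
The coefficient of determination of the CMI-only model, fitted on the sample
the CMIs were derived from, equals the between-group share of variance
(eta-squared) — the natural ceiling on what a grouping can explain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .casemix import CaseMixTable, case_mix_table
from .errors import ModelError
from .taxonomy import MEASURES

__all__ = ["attach_cmi", "r_squared", "evaluation_table"]


def attach_cmi(
    episode_table: pd.DataFrame, table: CaseMixTable
) -> tuple[pd.DataFrame, int]:
    """Add one predictor column ``cmi_<measure>`` per measure to each episode.

    Episodes whose group has an undefined (NA) CMI are excluded; the second
    return value counts them.
    """
    out = episode_table.copy()
    for m in MEASURES:
        out[f"cmi_{m}"] = out["group"].map(table.data[f"cmi_{m}"])
    cmi_cols = [f"cmi_{m}" for m in MEASURES]
    keep = out[cmi_cols].notna().all(axis=1)
    return out[keep].reset_index(drop=True), int((~keep).sum())


def _design_matrix(X: pd.DataFrame) -> pd.DataFrame:
    parts = []
    for col in X.columns:
        series = X[col]
        if pd.api.types.is_numeric_dtype(series):
            parts.append(series.astype(float))
        else:
            # dummy-encode with the most frequent level as reference
            reference = series.value_counts().idxmax()
            levels = [lv for lv in series.unique() if lv != reference]
            for lv in sorted(map(str, levels)):
                parts.append((series.astype(str) == lv).astype(float).rename(f"{col}[{lv}]"))
    return pd.concat(parts, axis=1)


def r_squared(outcome, predictors: pd.DataFrame) -> float:
    """Unadjusted OLS coefficient of determination, intercept included.

    Categorical predictor columns are dummy-encoded against their most
    frequent level. Degenerate designs (constant predictor, rank deficiency)
    or a constant outcome raise :class:`ModelError`.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ModelError("outcome has fewer than 2 distinct values")
    design = _design_matrix(pd.DataFrame(predictors))
    exog = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ModelError(
            "rank-deficient design (constant or collinear predictor column)"
        )
    return float(sm.OLS(y, exog).fit().rsquared)


def evaluation_table(
    full_sample: pd.DataFrame,
    operational_sample: pd.DataFrame,
    refit_cmi: bool = True,
    ddof: int = 1,
) -> pd.DataFrame:
    """The 4 measures x 2 models x 2 samples grid of variance explained.

    Both inputs are episode-level tables with ``group``, ``program_id`` and
    the four measure columns. With ``refit_cmi`` (default) the CMIs are
    re-derived within each sample before fitting; otherwise the full-sample
    CMIs are reused for the operational sample.
    """
    if len(full_sample) == 0 or len(operational_sample) == 0:
        raise ModelError("both samples must be non-empty")

    full_table = case_mix_table(full_sample, "full", ddof=ddof)
    results = []
    for label, sample in (("full", full_sample), ("operational", operational_sample)):
        table = (
            case_mix_table(sample, label, ddof=ddof)
            if (refit_cmi or label == "full")
            else full_table
        )
        aug, _ = attach_cmi(sample, table)
        for m in MEASURES:
            r2_cmi = r_squared(aug[m], aug[[f"cmi_{m}"]])
            r2_prog = r_squared(aug[m], aug[[f"cmi_{m}", "program_id"]])
            results.append({"measure": m, "model": "cmi_only", "sample": label,
                            "r_squared": r2_cmi, "n_used": len(aug)})
            results.append({"measure": m, "model": "cmi_plus_program", "sample": label,
                            "r_squared": r2_prog, "n_used": len(aug)})
    return pd.DataFrame(results)
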