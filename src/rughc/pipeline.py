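"""End-to-end orchestration: classify -> account -> index -> evaluate.

``run_pipeline`` takes either cohort CSV paths or a synthetic cohort config,
runs every stage for the full and the operational (length-trimmed) samples,
and writes all table analogs plus a run manifest (config hash, seed,
exclusion counts) to the output directory. Logging goes to stderr; results
only to files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ValidationError, model_validator

from .accounting import default_weights, episode_measures, load_rates, standardize_weights, trim_operational
from .casemix import case_mix_table
from .errors import ConfigurationError
from .grouper import classify_frame, distribution_table
from .io import read_cohort, write_cohort
from .rules import default_rules, load_rules
from .synthetic import CohortConfig, generate_cohort
from .taxonomy import DISCIPLINES, MEASURES
from .variance import evaluation_table

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("rughc.pipeline")


class PipelineConfig(BaseModel):
    assessments_path: Optional[str] = None
    billing_path: Optional[str] = None
    cohort: Optional[CohortConfig] = None
    rules_path: Optional[str] = None
    rates_path: Optional[str] = None
    unpaid_weight: float = 1.0
    low_trim: float = 0.01
    high_trim: float = 0.05
    cv_ddof: int = 1
    refit_cmi: bool = True
    outdir: str = "results/pipeline"
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        file_mode = self.assessments_path is not None and self.billing_path is not None
        if file_mode == (self.cohort is not None):
            raise ValueError("supply exactly one of (assessment+billing paths) or a cohort config")
        return self


def _config_hash(config: PipelineConfig) -> str:
    # outdir is presentation, not analysis: identical analyses hash identically
    payload = config.model_dump()
    payload.pop("outdir", None)
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _cohort_summary(assessments: pd.DataFrame, billing: pd.DataFrame,
                    measures: pd.DataFrame) -> pd.DataFrame:
    rows = [
        {"statistic": "episodes", "mean": len(assessments), "sd": ""},
        {"statistic": "episode_days", "mean": assessments["episode_days"].mean(),
         "sd": assessments["episode_days"].std(ddof=1)},
    ]
    if len(measures):
        for col, label in (("paid_hours", "paid_hours_per_episode"),
                           ("unpaid_hours", "unpaid_hours_per_episode")):
            rows.append({"statistic": label, "mean": measures[col].mean(),
                         "sd": measures[col].std(ddof=1)})
    per_episode = (
        billing.pivot_table(index="episode_id", columns="discipline", values="hours",
                            aggfunc="sum", fill_value=0.0)
        if len(billing) else pd.DataFrame(columns=list(DISCIPLINES))
    )
    for disc in DISCIPLINES:
        col = per_episode[disc] if disc in per_episode.columns else pd.Series(dtype=float)
        rows.append({"statistic": f"paid_hours_{disc}",
                     "mean": col.mean() if len(col) else 0.0,
                     "sd": col.std(ddof=1) if len(col) > 1 else 0.0})
    if "age" in assessments.columns and len(assessments):
        rows.append({"statistic": "age", "mean": assessments["age"].mean(),
                     "sd": assessments["age"].std(ddof=1)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run the full analysis; returns artifact paths and in-memory tables."""
    try:
        config = (PipelineConfig.model_validate(config.model_dump())
                  if isinstance(config, PipelineConfig)
                  else PipelineConfig.model_validate(config))
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc

    rules = load_rules(config.rules_path) if config.rules_path else default_rules()
    weights = (standardize_weights(load_rates(config.rates_path), config.unpaid_weight)
               if config.rates_path else default_weights(config.unpaid_weight))
    os.makedirs(config.outdir, exist_ok=True)

    row_errors: list[str] = []
    if config.cohort is not None:
        cohort_cfg = config.cohort
        if config.seed is not None:
            cohort_cfg = cohort_cfg.model_copy(update={"seed": config.seed})
        log.info("generating synthetic cohort: n=%d seed=%d",
                 cohort_cfg.n_episodes, cohort_cfg.seed)
        assessments, billing = generate_cohort(cohort_cfg)
        write_cohort(assessments, billing, os.path.join(config.outdir, "cohort"))
    else:
        log.info("reading cohort from %s / %s", config.assessments_path, config.billing_path)
        result = read_cohort(config.assessments_path, config.billing_path, rules)
        assessments, billing, row_errors = result.assessments, result.billing, result.row_errors

    artifacts: dict = {}

    # classification
    groups = classify_frame(assessments, rules)
    groups.to_csv(os.path.join(config.outdir, "episode_groups.csv"))
    dist_full = distribution_table(groups.tolist())
    dist_full.to_csv(os.path.join(config.outdir, "distribution_full.csv"), index=False)

    # operational sample: trim on episode length over the whole cohort
    operational = trim_operational(assessments, config.low_trim, config.high_trim)
    n_trimmed = len(assessments) - len(operational)
    dist_oper = distribution_table(groups.loc[operational["episode_id"]].tolist())
    dist_oper.to_csv(os.path.join(config.outdir, "distribution_operational.csv"), index=False)

    # accounting (billing-complete episodes only)
    measures, n_missing_billing = episode_measures(assessments, billing, weights)
    measures = measures.merge(groups.rename("group"), left_on="episode_id", right_index=True)
    measures.to_csv(os.path.join(config.outdir, "episode_measures.csv"), index=False)
    oper_ids = set(operational["episode_id"])
    measures_oper = measures[measures["episode_id"].isin(oper_ids)].reset_index(drop=True)

    summary = _cohort_summary(assessments, billing, measures)
    summary.to_csv(os.path.join(config.outdir, "cohort_summary.csv"), index=False)

    if len(measures) == 0 or len(measures_oper) == 0:
        log.warning("no billing-complete episodes; case-mix and evaluation outputs are empty")
        for name in ("casemix_full.csv", "casemix_operational.csv", "evaluation.csv"):
            pd.DataFrame().to_csv(os.path.join(config.outdir, name), index=False)
        cmx_full = cmx_oper = None
        evaluation = pd.DataFrame()
    else:
        cmx_full = case_mix_table(measures, "full", ddof=config.cv_ddof)
        cmx_oper = case_mix_table(measures_oper, "operational", ddof=config.cv_ddof)
        cmx_full.data.to_csv(os.path.join(config.outdir, "casemix_full.csv"))
        cmx_oper.data.to_csv(os.path.join(config.outdir, "casemix_operational.csv"))
        evaluation = evaluation_table(measures, measures_oper,
                                      refit_cmi=config.refit_cmi, ddof=config.cv_ddof)
        evaluation = evaluation.assign(
            r_squared_pct=(100 * evaluation["r_squared"]).round(2)
        )
        evaluation.to_csv(os.path.join(config.outdir, "evaluation.csv"), index=False)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": (config.cohort.seed if config.cohort is not None else None)
        if config.seed is None else config.seed,
        "n_episodes": int(len(assessments)),
        "n_classified": int(len(groups)),
        "n_missing_billing": int(n_missing_billing),
        "n_trimmed": int(n_trimmed),
        "n_operational": int(len(operational)),
        "n_casemix_full": int(len(measures)),
        "n_casemix_operational": int(len(measures_oper)),
        "n_row_errors": len(row_errors),
        "measures": list(MEASURES),
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    artifacts.update(
        outdir=config.outdir, manifest=manifest,
        assessments=assessments, billing=billing, groups=groups,
        distribution_full=dist_full, distribution_operational=dist_oper,
        measures_full=measures, measures_operational=measures_oper,
        casemix_full=cmx_full, casemix_operational=cmx_oper,
        evaluation=evaluation, row_errors=row_errors,
    )
    return artifacts
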