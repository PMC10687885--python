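"""Shared test utilities: record builders and independent oracles.

The oracles here deliberately re-derive results from first principles (raw
YAML walking, direct sum-of-squares decompositions) so they share no code
path with the implementation they check.
"""

from __future__ import annotations

import numpy as np

from rughc.records import AssessmentRecord

# ADL item vectors (4 items, codes 1-5, unit weights) landing in each band
# under the default cut-points A<=7 < B<=12 < C<=16 < D.
ADL_VECTORS = {
    "A": [(1, 1, 1, 1), (1, 1, 1, 4)],          # sums 4, 7
    "B": [(2, 2, 2, 2), (3, 3, 3, 3)],          # sums 8, 12
    "C": [(4, 3, 3, 3), (4, 4, 4, 4)],          # sums 13, 16
    "D": [(5, 4, 4, 4), (5, 5, 5, 5)],          # sums 17, 20
}

IADL_VECTORS = {"none": [(0, 0, 0)], "some": [(1, 0, 0), (3, 3, 3)]}


def make_record(
    rules,
    adl=(1, 1, 1, 1),
    iadl=(0, 0, 0),
    clinical=(),
    behaviour=(),
    therapy=0.0,
    cognition=0,
    episode_id="E1",
    days=100,
    unpaid_adm=0.0,
    unpaid_dis=None,
) -> AssessmentRecord:
    """An AssessmentRecord with explicit item codes under the given rule config."""
    return AssessmentRecord(
        episode_id=episode_id,
        client_id="C1",
        program_id="P1",
        episode_days=days,
        adl_items=dict(zip(rules.adl_scale.items, adl)),
        iadl_items=dict(zip(rules.iadl_scale.items, iadl)),
        cognitive_performance=cognition,
        behaviour_flags=set(behaviour),
        clinical_flags=set(clinical),
        therapy_minutes_7day=therapy,
        unpaid_hours_3day_admission=unpaid_adm,
        unpaid_hours_3day_discharge=unpaid_dis,
    )


def oracle_classify(raw: dict, adl: dict, iadl: dict, clinical: set, behaviour: set,
                    therapy: float, cognition: int) -> str:
    """Brute-force re-evaluation of the raw YAML rule table (no rughc code)."""
    adl_cfg = raw["adl_scale"]
    weights = adl_cfg.get("weights") or {i: 1.0 for i in adl_cfg["items"]}
    score = sum(weights[i] * adl[i] for i in adl_cfg["items"])
    cp = adl_cfg["band_cutpoints"]
    if score <= cp["A"]:
        band = "A"
    elif score <= cp["B"]:
        band = "B"
    elif score <= cp["C"]:
        band = "C"
    else:
        band = "D"

    cut = raw["iadl_scale"]["difficulty_cutpoint"]
    iadl_band = "some" if any(iadl[i] >= cut for i in raw["iadl_scale"]["items"]) else "none"

    ext = []
    for cat in raw["categories"]:
        if cat["name"] == "ExtensiveServices":
            ext = cat["trigger"].get("clinical_any", [])
    n_svc = len(clinical & set(ext))

    for cat in raw["categories"]:
        trig = cat["trigger"]
        hit = bool(trig.get("always"))
        if "therapy_minutes_min" in trig and therapy >= trig["therapy_minutes_min"]:
            hit = True
        if trig.get("clinical_any") and clinical & set(trig["clinical_any"]):
            hit = True
        if trig.get("behaviour_any") and behaviour & set(trig["behaviour_any"]):
            hit = True
        if "cognitive_performance_min" in trig and cognition >= trig["cognitive_performance_min"]:
            hit = True
        if not hit:
            continue
        for sp in cat["splits"]:
            if "adl_bands" in sp and band not in sp["adl_bands"]:
                continue
            if sp.get("iadl", "any") not in ("any", iadl_band):
                continue
            if sp.get("services_min") is not None and n_svc < sp["services_min"]:
                continue
            return sp["group"]
        raise AssertionError(f"oracle: no split matched in {cat['name']}")
    raise AssertionError("oracle: no category triggered")


def eta_squared(values, labels) -> float:
    """Between-group sum of squares over total sum of squares, from scratch."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_between = 0.0
    for g in np.unique(labels):
        sub = values[labels == g]
        ss_between += len(sub) * (sub.mean() - grand) ** 2
    return ss_between / ss_total
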