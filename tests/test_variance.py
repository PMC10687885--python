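"""Variance explained by the case-mix system: R^2 mechanics and properties."""

import numpy as np
import pandas as pd
import pytest

from helpers import eta_squared
from rughc import (
    CohortConfig,
    ModelError,
    attach_cmi,
    case_mix_table,
    classify_frame,
    default_rules,
    default_weights,
    episode_measures,
    evaluation_table,
    generate_cohort,
    r_squared,
    trim_operational,
)
from rughc.taxonomy import MEASURES


def build_episode_table(config):
    assessments, billing = generate_cohort(config)
    rules = default_rules()
    groups = classify_frame(assessments, rules)
    measures, _ = episode_measures(assessments, billing, default_weights())
    merged = measures.merge(groups.rename("group"), left_on="episode_id", right_index=True)
    return assessments, merged


class TestRSquared:
    def test_outcome_equal_to_predictor(self):
        y = np.arange(10, dtype=float)
        assert r_squared(y, pd.DataFrame({"x": y})) == pytest.approx(1.0, abs=1e-12)

    def test_constant_predictor_is_model_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ModelError):
            r_squared(rng.normal(size=20), pd.DataFrame({"x": np.ones(20)}))

    def test_constant_outcome_is_model_error(self):
        with pytest.raises(ModelError):
            r_squared(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_categorical_predictor_dummy_encoded(self):
        y = np.array([1.0, 1.1, 0.9, 5.0, 5.2, 4.8])
        prog = pd.DataFrame({"program_id": ["A", "A", "A", "B", "B", "B"]})
        r2 = r_squared(y, prog)
        assert r2 == pytest.approx(eta_squared(y, prog["program_id"]), abs=1e-10)


class TestEtaSquaredEquivalence:
    def test_cmi_regression_matches_brute_force_decomposition(self):
        """R^2 of measure ~ own-group CMI equals between-group SS / total SS."""
        rng = np.random.default_rng(123)
        groups = ["CA1"] * 10 + ["CB"] * 10 + ["PD"] * 10
        values = np.concatenate([
            rng.gamma(4, 10, 10), rng.gamma(6, 12, 10), rng.gamma(9, 15, 10)
        ])
        df = pd.DataFrame({"group": groups, **{m: values for m in MEASURES}})
        table = case_mix_table(df)
        aug, n_excluded = attach_cmi(df, table)
        assert n_excluded == 0
        for m in MEASURES:
            r2 = r_squared(aug[m], aug[[f"cmi_{m}"]])
            assert r2 == pytest.approx(eta_squared(values, groups), abs=1e-10)


class TestAttachCmi:
    def test_lookup_value(self, episode_table, casemix):
        aug, _ = attach_cmi(episode_table, casemix)
        one = aug.iloc[0]
        assert one["cmi_paid_hours"] == pytest.approx(
            casemix.cmi(one["group"], "paid_hours")
        )

    def test_single_group_gives_constant_predictor(self):
        df = pd.DataFrame({"group": ["CA1"] * 8, **{m: range(8) for m in MEASURES}})
        aug, _ = attach_cmi(df, case_mix_table(df))
        assert aug["cmi_paid_hours"].nunique() == 1

    def test_na_group_episodes_excluded_and_counted(self, episode_table):
        # derive CMIs from a subsample that misses some group entirely
        present = episode_table["group"].value_counts()
        drop_group = present.index[0]
        sub = episode_table[episode_table["group"] != drop_group]
        table = case_mix_table(sub)
        aug, n_excluded = attach_cmi(episode_table, table)
        assert n_excluded == int(present.iloc[0])
        assert len(aug) == len(episode_table) - n_excluded


class TestEvaluationTable:
    def test_full_grid_shape(self, episode_table):
        oper = episode_table[episode_table["episode_days"] <= episode_table["episode_days"].quantile(0.95)]
        table = evaluation_table(episode_table, oper)
        assert len(table) == 16
        assert set(table["model"]) == {"cmi_only", "cmi_plus_program"}
        assert set(table["sample"]) == {"full", "operational"}
        assert ((table["r_squared"] >= 0) & (table["r_squared"] <= 1)).all()

    def test_program_indicator_never_decreases_r2(self, episode_table):
        oper = trim_operational(episode_table)
        table = evaluation_table(episode_table, oper)
        for (m, s), sub in table.groupby(["measure", "sample"]):
            r2 = sub.set_index("model")["r_squared"]
            assert r2["cmi_plus_program"] >= r2["cmi_only"] - 1e-10

    def test_program_multipliers_raise_program_model_r2(self):
        """Strong program-level effects make the program indicator informative."""
        cfg = CohortConfig(
            n_episodes=3000, seed=31, n_programs=3,
            program_effect_multipliers=[0.5, 1.0, 2.0],
            missing_billing_rate=0.0,
        )
        _, merged = build_episode_table(cfg)
        oper = trim_operational(merged)
        table = evaluation_table(merged, oper)
        gains = {}
        for (m, s), sub in table.groupby(["measure", "sample"]):
            r2 = sub.set_index("model")["r_squared"]
            gains[(m, s)] = r2["cmi_plus_program"] - r2["cmi_only"]
        # program multipliers scale paid care only, so the gain is largest
        # there; unpaid care dilutes it in the combined measures
        for m in ("paid_hours", "paid_cost"):
            for s in ("full", "operational"):
                assert gains[(m, s)] > 0.05
        assert min(gains.values()) > 0.01  # still beyond dummy-fitting noise

    def test_no_program_signal_means_similar_r2(self):
        cfg = CohortConfig(n_episodes=2000, seed=17, missing_billing_rate=0.0)
        _, merged = build_episode_table(cfg)
        oper = trim_operational(merged)
        table = evaluation_table(merged, oper)
        for (m, s), sub in table.groupby(["measure", "sample"]):
            r2 = sub.set_index("model")["r_squared"]
            assert r2["cmi_plus_program"] - r2["cmi_only"] < 0.02

    def test_combined_care_explains_more_than_paid_alone(self):
        """With the documented case-mix structure (unpaid care far more
        strongly differentiated across groups than paid care), the combined
        measures have higher R^2 than the paid-only ones, and trimming
        length-of-stay outliers raises R^2 for every measure."""
        cfg = CohortConfig(n_episodes=3000, seed=99, missing_billing_rate=0.0)
        _, merged = build_episode_table(cfg)
        oper = trim_operational(merged)
        table = evaluation_table(merged, oper)
        r2 = table[table["model"] == "cmi_only"].set_index(["measure", "sample"])["r_squared"]
        for sample in ("full", "operational"):
            assert r2[("total_hours", sample)] > r2[("paid_hours", sample)]
            assert r2[("total_cost", sample)] > r2[("paid_cost", sample)]
        for measure in ("paid_hours", "paid_cost", "total_hours", "total_cost"):
            assert r2[(measure, "operational")] >= r2[(measure, "full")]

    def test_deterministic_outcome_gives_r2_one(self):
        df = pd.DataFrame({"group": ["CA1"] * 10 + ["CC"] * 10,
                           "program_id": ["P1"] * 20,
                           **{m: [3.0] * 10 + [9.0] * 10 for m in MEASURES}})
        table = evaluation_table(df, df)
        cmi_only = table[table["model"] == "cmi_only"]
        assert np.allclose(cmi_only["r_squared"], 1.0, atol=1e-10)
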