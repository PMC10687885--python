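"""Cost weights, paid/unpaid measures, and length-of-stay trimming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rughc import (
    ConfigurationError,
    DataError,
    estimate_unpaid_hours,
    paid_measures,
    standardize_weights,
    trim_operational,
)


class TestStandardizeWeights:
    def test_psw_weight_is_exactly_one(self):
        w = standardize_weights({"PSW": 31.7, "RN": 74.2})
        assert w.weight["PSW"] == 1.0

    def test_equal_rates_give_unit_weights(self):
        w = standardize_weights({d: 40.0 for d in ("PSW", "RN", "OT")})
        assert all(v == 1.0 for v in w.weight.values())

    def test_direct_ratio(self):
        w = standardize_weights({"PSW": 25.0, "RN": 50.0})
        assert w.weight["RN"] == 2.0

    def test_invariant_to_common_rescaling(self):
        rates = {"PSW": 30.0, "RN": 75.0, "OT": 90.0}
        w1 = standardize_weights(rates)
        w2 = standardize_weights({d: 3.5 * r for d, r in rates.items()})
        for d in rates:
            assert w1.weight[d] == pytest.approx(w2.weight[d], abs=1e-12)

    def test_unpaid_weight_defaults_to_one(self):
        assert standardize_weights({"PSW": 30.0}).unpaid_weight == 1.0

    def test_missing_psw_rejected(self):
        with pytest.raises(ConfigurationError, match="PSW"):
            standardize_weights({"RN": 50.0})

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ConfigurationError, match="RN"):
            standardize_weights({"PSW": 30.0, "RN": 0.0})


class TestPaidMeasures:
    def test_empty_billing(self, weights):
        assert paid_measures(pd.DataFrame(columns=["discipline", "hours"]), weights) == (0.0, 0.0)

    def test_worked_example(self):
        w = standardize_weights({"PSW": 25.0, "RN": 50.0})
        billing = pd.DataFrame({"discipline": ["PSW", "RN"], "hours": [3.0, 4.0]})
        assert paid_measures(billing, w) == (7.0, 11.0)

    def test_unit_weights_make_cost_equal_hours(self):
        w = standardize_weights({d: 40.0 for d in ("PSW", "RN", "PT")})
        rng = np.random.default_rng(0)
        billing = pd.DataFrame({
            "discipline": rng.choice(["PSW", "RN", "PT"], 30),
            "hours": rng.uniform(0, 10, 30).round(2),
        })
        hours, cost = paid_measures(billing, w)
        assert cost == pytest.approx(hours, abs=1e-9)

    def test_unknown_discipline_named(self, weights):
        billing = pd.DataFrame({"discipline": ["XX"], "hours": [1.0]})
        with pytest.raises(DataError, match="XX"):
            paid_measures(billing, weights)


class TestEstimateUnpaidHours:
    def test_zero_reports(self):
        assert estimate_unpaid_hours(0.0, 0.0, 200) == 0.0

    def test_admission_and_discharge_averaged(self):
        # mean(6, 12)/3 per day x 100 days
        assert estimate_unpaid_hours(6.0, 12.0, 100) == pytest.approx(300.0)

    def test_admission_only_fallback(self):
        assert estimate_unpaid_hours(9.0, None, 30) == pytest.approx(90.0)

    def test_negative_report_rejected(self):
        with pytest.raises(DataError):
            estimate_unpaid_hours(-1.0, 0.0, 10)


class TestTrimOperational:
    @staticmethod
    def frame(lengths):
        return pd.DataFrame({"episode_id": range(len(lengths)), "episode_days": lengths})

    def test_zero_fractions_identity(self):
        df = self.frame(range(1, 51))
        assert len(trim_operational(df, 0.0, 0.0)) == 50

    def test_explicit_1_to_100_vector(self):
        """1..100 days at 1%/5% trims exactly {1} and {96..100}: 94 retained."""
        kept = trim_operational(self.frame(range(1, 101)), 0.01, 0.05)
        days = set(kept["episode_days"])
        assert len(kept) == 94
        assert 1 not in days and days.isdisjoint(range(96, 101))
        assert {2, 95} <= days

    def test_identical_lengths_untouched(self):
        assert len(trim_operational(self.frame([30] * 40), 0.01, 0.05)) == 40

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            trim_operational(self.frame([1, 2, 3]), 0.6, 0.5)
        with pytest.raises(ConfigurationError):
            trim_operational(self.frame([1, 2, 3]), -0.1, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        lengths=st.lists(st.integers(1, 500), min_size=5, max_size=60),
        low=st.floats(0.0, 0.2),
        high=st.floats(0.0, 0.2),
    )
    def test_retained_size_monotone_in_trim_fractions(self, lengths, low, high):
        """Trimming harder never retains more episodes."""
        df = self.frame(lengths)
        base = len(trim_operational(df, low, high))
        assert len(trim_operational(df, min(low + 0.05, 0.5), high)) <= base
        assert len(trim_operational(df, low, min(high + 0.05, 0.5))) <= base


def test_mean_unpaid_hours_matches_documented_order_of_magnitude(episode_table):
    """Default generator settings put unpaid care near 3.5 h/day x ~99 days."""
    mean_unpaid = episode_table["unpaid_hours"].mean()
    assert 150 < mean_unpaid < 700  # ~350 h with heavy right skew
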