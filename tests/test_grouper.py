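"""Classification hierarchy, scales, and the distribution table."""

import itertools

import pytest

from helpers import ADL_VECTORS, make_record
from rughc import (
    ClassificationError,
    adl_score,
    classify_episode,
    distribution_table,
    iadl_band,
)
from rughc.reference import REFERENCE_GROUP_COUNTS_FULL
from rughc.rules import RuleConfig
from rughc.taxonomy import CATEGORY_GROUPS, CATEGORY_ORDER, GROUPS


class TestAdlScore:
    def test_floor_is_band_a(self, rules):
        score, band = adl_score(make_record(rules, adl=(1, 1, 1, 1)), rules)
        assert score == 4 and band == "A"

    def test_ceiling_is_band_d(self, rules):
        score, band = adl_score(make_record(rules, adl=(5, 5, 5, 5)), rules)
        assert score == 20 and band == "D"

    def test_band_never_decreases_along_single_item_increments(self, rules):
        """Raising any one item code can only keep or raise the band."""
        order = {"A": 0, "B": 1, "C": 2, "D": 3}
        for base in itertools.product(range(1, 6), repeat=4):
            _, band = adl_score(make_record(rules, adl=base), rules)
            for pos in range(4):
                if base[pos] == 5:
                    continue
                bumped = list(base)
                bumped[pos] += 1
                _, band2 = adl_score(make_record(rules, adl=bumped), rules)
                assert order[band2] >= order[band]

    def test_missing_item_names_it(self, rules):
        record = make_record(rules)
        del record.adl_items[rules.adl_scale.items[0]]
        with pytest.raises(ClassificationError, match=rules.adl_scale.items[0]):
            adl_score(record, rules)

    def test_out_of_range_code_rejected(self, rules):
        with pytest.raises(ClassificationError):
            adl_score(make_record(rules, adl=(0, 1, 1, 1)), rules)


class TestIadlBand:
    def test_all_zero_is_none(self, rules):
        assert iadl_band(make_record(rules, iadl=(0, 0, 0)), rules) == "none"

    @pytest.mark.parametrize("codes", [(1, 0, 0), (0, 3, 0), (0, 0, 2)])
    def test_any_item_at_cutpoint_is_some(self, rules, codes):
        assert iadl_band(make_record(rules, iadl=codes), rules) == "some"

    def test_two_item_grid_matches_definition(self, rules):
        """Exhaustive grid over two items agrees with the literal definition."""
        cut = rules.iadl_scale.difficulty_cutpoint
        for a, b in itertools.product(range(4), repeat=2):
            got = iadl_band(make_record(rules, iadl=(a, b, 0)), rules)
            assert got == ("some" if a >= cut or b >= cut else "none")


class TestClassifyEpisode:
    def test_no_triggers_low_function_is_pa1(self, rules):
        group = classify_episode(make_record(rules), rules)
        assert group.code == "PA1"
        assert group.category.name == "ReducedPhysicalFunctions"

    def test_clinically_complex_low_adl_some_iadl_is_ca2(self, rules):
        record = make_record(rules, clinical={"pneumonia"}, iadl=(1, 0, 0))
        assert classify_episode(record, rules).code == "CA2"

    def test_rehabilitation_outranks_clinically_complex(self, rules):
        record = make_record(rules, therapy=150.0, clinical={"pneumonia"})
        assert classify_episode(record, rules).category.name == "Rehabilitation"

    def test_extensive_services_split_counts_distinct_services(self, rules):
        ext = rules.extensive_services
        for k, expected in ((1, "SE1"), (2, "SE2"), (3, "SE3")):
            record = make_record(rules, clinical=set(ext[:k]))
            assert classify_episode(record, rules).code == expected

    def test_adding_higher_rank_trigger_never_lowers_category(self, rules):
        """Hierarchy dominance: planting a higher-priority trigger can only
        move the episode to an equal- or higher-priority category."""
        base = make_record(rules, clinical={"pneumonia"}, adl=(2, 2, 2, 2))
        base_rank = classify_episode(base, rules).category.rank
        boosted = make_record(rules, clinical={"pneumonia", "iv_medication"}, adl=(2, 2, 2, 2))
        assert classify_episode(boosted, rules).category.rank <= base_rank

    def test_every_band_iadl_combination_yields_exactly_one_group(self, rules):
        for band, iadl_key in itertools.product("ABCD", ["none", "some"]):
            adl = ADL_VECTORS[band][0]
            iadl = (0, 0, 0) if iadl_key == "none" else (2, 0, 0)
            group = classify_episode(make_record(rules, adl=adl, iadl=iadl), rules)
            assert group.code in GROUPS


class TestRuleConfigValidation:
    def test_default_taxonomy_shape(self, rules):
        assert [c.name for c in rules.categories] == list(CATEGORY_ORDER)
        assert tuple(len(CATEGORY_GROUPS[c]) for c in CATEGORY_ORDER) == (3, 3, 2, 4, 3, 3, 5)
        assert len(GROUPS) == 23

    def test_non_total_split_map_rejected(self, raw_rules):
        broken = {**raw_rules, "categories": [dict(c) for c in raw_rules["categories"]]}
        # drop the terminal category's band-D rule -> unreachable combination
        rpf = dict(broken["categories"][-1])
        rpf["splits"] = [s for s in rpf["splits"] if s["group"] != "PD"]
        broken["categories"][-1] = rpf
        with pytest.raises(Exception, match="not total|unreachable"):
            RuleConfig.model_validate(broken)

    def test_terminal_category_must_be_catch_all(self, raw_rules):
        broken = {**raw_rules, "categories": [dict(c) for c in raw_rules["categories"]]}
        rpf = dict(broken["categories"][-1])
        rpf["trigger"] = {"cognitive_performance_min": 99}
        broken["categories"][-1] = rpf
        with pytest.raises(Exception, match="always-true"):
            RuleConfig.model_validate(broken)


class TestDistributionTable:
    def test_reference_counts_reproduce_published_percentages(self):
        table = distribution_table(REFERENCE_GROUP_COUNTS_FULL).set_index("label")
        assert table.loc["ClinicallyComplex", "percentage"] == 41.6
        assert table.loc["ReducedPhysicalFunctions", "percentage"] == 37.8
        assert table.loc["Rehabilitation", "percentage"] == 10.4
        assert table.loc["CA2", "percentage"] == 20.1
        assert table.loc["Total", "count"] == 1680

    def test_single_episode(self):
        table = distribution_table(["CC"]).set_index("label")
        assert table.loc["CC", "percentage"] == 100.0
        assert table.loc["PA1", "percentage"] == 0.0
        assert table.loc["Total", "count"] == 1

    def test_empty_input(self):
        table = distribution_table([]).set_index("label")
        assert table.loc["Total", "count"] == 0
        assert table.loc["Total", "percentage"] == 0.0

    def test_counts_sum_and_categories_aggregate(self, small_cohort, rules):
        from rughc import classify_frame

        assessments, _ = small_cohort
        groups = classify_frame(assessments, rules)
        table = distribution_table(groups.tolist())
        assert table[table.level == "group"]["count"].sum() == len(assessments)
        for cat in CATEGORY_ORDER:
            cat_n = table[(table.level == "category") & (table.label == cat)]["count"].iloc[0]
            group_n = table[(table.level == "group") & (table.category == cat)]["count"].sum()
            assert cat_n == group_n
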