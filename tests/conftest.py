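import importlib.resources

import pytest
import yaml

from rughc import (
    CohortConfig,
    case_mix_table,
    classify_frame,
    default_rules,
    default_weights,
    episode_measures,
    generate_cohort,
)


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def raw_rules():
    """The default rule YAML as a plain dict, for independent oracle walks."""
    text = (
        importlib.resources.files("rughc").joinpath("data/rules_default.yaml").read_text("utf-8")
    )
    return yaml.safe_load(text)


@pytest.fixture(scope="session")
def weights():
    return default_weights()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-episode synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_episodes=400, seed=7))


@pytest.fixture(scope="session")
def episode_table(small_cohort, rules, weights):
    """Billing-complete episode-level utilization table with group labels."""
    assessments, billing = small_cohort
    measures, _ = episode_measures(assessments, billing, weights)
    groups = classify_frame(assessments, rules)
    return measures.merge(groups.rename("group"), left_on="episode_id", right_index=True)


@pytest.fixture(scope="session")
def casemix(episode_table):
    return case_mix_table(episode_table, "full")
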