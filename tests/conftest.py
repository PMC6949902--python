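import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dietscreen import (
    default_composition,
    default_criteria,
    default_ffq_schema,
    default_sdq_schema,
    default_thresholds,
)


@pytest.fixture(scope="session")
def ffq_schema():
    return default_ffq_schema()


@pytest.fixture(scope="session")
def sdq_schema():
    return default_sdq_schema()


@pytest.fixture(scope="session")
def composition():
    return default_composition()


@pytest.fixture(scope="session")
def criteria():
    return default_criteria()


@pytest.fixture(scope="session")
def thresholds():
    return default_thresholds()


def all_never_response(schema, rid="p1", age=75, **overrides):
    """FFQ response answering every item 'Never' except the given overrides."""
    answers = {iid: "Never" for iid in schema.item_ids}
    answers.update(overrides)
    from dietscreen import RespondentResponse

    return RespondentResponse(respondent_id=rid, age_years=age, answers=answers)
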