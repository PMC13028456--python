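import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

from marie import load_reference_table  # noqa: E402


@pytest.fixture(scope="session")
def table_2012_2021():
    return load_reference_table("FY2012-FY2021")


@pytest.fixture(scope="session")
def table_2015_2024():
    return load_reference_table("FY2015-FY2024")


@pytest.fixture
def max_assessment_doc():
    """All twelve elements at their highest-scoring level (50 + 50 points)."""
    return {
        "drug_id": "DEMO-MAX",
        "efficacy": "superiority",
        "safety": "acceptable_with_surveillance",
        "scientific_novelty": "novel_mechanism",
        "clinical_positioning": "new_option",
        "unmet_needs": "low_satisfaction_low_contribution",
        "qol": "improved",
        "true_endpoints": "improved",
        "productivity_loss": "reports_available",
        "convenience": "improved",
        "diagnosis": "improved",
        "pediatric_use": "approved",
        "others": {"level": "applicable",
                   "justification": "first disease-modifying therapy"},
    }


@pytest.fixture
def min_assessment_doc():
    """Base elements at their lowest levels, no additional value claimed."""
    return {
        "drug_id": "DEMO-MIN",
        "efficacy": "single_arm",
        "safety": "acceptable_with_warnings",
        "scientific_novelty": "efficacy_shown",
        "clinical_positioning": "one_of_several",
    }
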