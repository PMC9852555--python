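import pytest

from geritox import CohortSpec, generate_cohort
from geritox.records import PatientRecord


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic synthetic cohort shared across evaluation tests."""
    return generate_cohort(CohortSpec(n=200, seed=3))


def make_patient(**overrides) -> PatientRecord:
    """A fully-specified fit 71-year-old; override fields per test."""
    base = dict(
        age=71,
        sex="female",
        cancer_type="breast",
        stage="2",
        ecog_ps=1,
        hemoglobin=12.5,
        creatinine_clearance=80.0,
        albumin=40.0,
        ldh=150.0,
        falls_past_6mo=False,
        hearing_fair_or_worse=False,
        walking_one_block_limited=False,
        needs_help_medications=False,
        decreased_social_activity=False,
        polychemotherapy=False,
        standard_dose=False,
    )
    base.update(overrides)
    return PatientRecord(**base)
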