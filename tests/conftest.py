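import numpy as np
import pytest

from oncofusion import SimConfig, generate_cohort, PatientRecord


@pytest.fixture(scope="session")
def small_cohort():
    """80-patient synthetic cohort with default missingness."""
    return generate_cohort(SimConfig(n_patients=80, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """120-patient cohort with no missingness (every vector complete)."""
    return generate_cohort(SimConfig(n_patients=120, seed=12, missing_rates={}))


def make_record(pid="0001", **overrides):
    """Minimal valid patient record for targeted field tests."""
    base = dict(
        patient_id=pid,
        sex="male",
        age_at_diagnosis=61,
        smoking_status="former",
        primary_site="larynx",
        followup_days=1500,
        pt_stage="pT2",
        pn_stage="pN0",
        grading="G2",
        lymphatic_invasion=False,
        vascular_invasion=False,
        perineural_invasion=False,
        carcinoma_in_situ=False,
        hpv_positive=False,
        resection_margin_positive=False,
        blood={"hemoglobin": {"value": 14.1, "unit": "g/dL", "group": "hematology"}},
        icd_codes=["C32.0"],
        tma_density={"CD3_tumor_center": 500.0, "CD3_invasion_front": 300.0,
                     "CD8_tumor_center": 200.0, "CD8_invasion_front": 100.0},
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record
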