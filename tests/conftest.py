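from datetime import timedelta

import pytest

import mipdkit as mk


@pytest.fixture(scope="session")
def epoch():
    return mk.EPOCH


@pytest.fixture
def typical_cov():
    """70 kg, 40-year-old man with a measured CLcr of 100 mL/min."""
    return mk.CovariateSet(
        weight_kg=70.0,
        serum_creatinine_mg_dL=1.0,
        age_years=40.0,
        sex=mk.Sex.MALE,
        clcr_ml_min=100.0,
        time=mk.EPOCH,
    )


@pytest.fixture
def typical_patient(typical_cov):
    return mk.PatientRecord(id="test-patient", covariates=[typical_cov])


@pytest.fixture
def vanc_params(typical_cov):
    return mk.compute_individual_parameters(mk.get_model("vancomycin"), typical_cov)


def hours(h: float):
    return mk.EPOCH + timedelta(hours=h)
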