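from datetime import date

import pytest

import ckmstage as ck


@pytest.fixture(scope="session")
def registry():
    return ck.default_registry()


@pytest.fixture
def index():
    return ck.IndexSpec(index_date=date(2026, 1, 1), lookback_months=24)


@pytest.fixture
def config(index):
    return ck.StagingConfig(index=index)


def make_history(patient_id, rows):
    """rows: (claim_id, iso_date, setting, codes)"""
    claims = tuple(
        ck.ClaimRecord(patient_id, cid, date.fromisoformat(d), setting, tuple(codes))
        for cid, d, setting, codes in rows
    )
    return ck.PatientHistory(patient_id, claims)


@pytest.fixture
def worked_example_history():
    """The claims-only use-case patient: confirmed hypertension and diabetes,
    one obesity claim with a BMI code, and an inpatient AMI; no kidney
    failure codes. Index 2026-01-01, 24-month lookback."""
    return make_history(
        "PT1",
        [
            ("c1", "2025-03-01", "outpatient", ["I10"]),
            ("c2", "2025-04-15", "outpatient", ["I10"]),  # 45 days apart
            ("c3", "2025-05-01", "outpatient", ["E119"]),
            ("c4", "2025-06-30", "outpatient", ["E119"]),  # 60 days apart
            ("c5", "2025-07-10", "outpatient", ["E66813", "Z6841"]),
            ("c6", "2025-08-20", "inpatient", ["I213"]),
        ],
    )


@pytest.fixture
def contrast_history():
    """Confirmed obesity only, no stage 2-4 core codes."""
    return make_history(
        "PT2",
        [
            ("d1", "2025-03-01", "outpatient", ["E669"]),
            ("d2", "2025-05-01", "outpatient", ["E669"]),
        ],
    )
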