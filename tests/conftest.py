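import numpy as np
import pytest

from icurfd.pipeline import RunConfig, prepare_dataset
from icurfd.records import PatientStay
from icurfd.synth import generate_cohort, gicu_like, mimic_like


@pytest.fixture(scope="session")
def mimic5000():
    """Large default-parameter cohort shared by prevalence/augmentation tests."""
    return generate_cohort(mimic_like(n_patients=5000, seed=101))


@pytest.fixture(scope="session")
def small_cohorts():
    a = generate_cohort(mimic_like(n_patients=150, seed=7))
    b = generate_cohort(gicu_like(n_patients=100, seed=8))
    return a, b


@pytest.fixture(scope="session")
def small_df(small_cohorts):
    """Imputed feature matrix over both small cohorts (all 22 features)."""
    cfg = RunConfig(
        cohort_a=mimic_like(n_patients=150, seed=7),
        cohort_b=gicu_like(n_patients=100, seed=8),
        seed=0,
    )
    df, _ = prepare_dataset(cfg)
    return df


#: Feature values sitting exactly on every printed test bound (all pass).
BOUNDARY_PASSING = {
    "airway": 1.0,
    "fio2": 0.6,
    "spo2_min": 95.0,
    "hco3": 19.0,
    "resp_min": 10.0,
    "resp_max": 30.0,
    "bp_min": 100.0,
    "hr_min": 60.0,
    "hr_max": 100.0,
    "pain": 1.0,
    "gcs_min": 14.0,
    "temp_min": 36.0,
    "temp_max": 37.5,
    "haemoglobin": 90.0,
    "k": 3.5,
    "na": 130.0,
    "creatinine": 59.0,
    "bun": 2.5,
}

#: One out-of-bound value per feature (violates exactly that feature's test).
BOUNDARY_VIOLATIONS = {
    "airway": 0.0,
    "fio2": 0.61,
    "spo2_min": 94.9,
    "hco3": 18.9,
    "resp_min": 9.9,
    "resp_max": 30.1,
    "bp_min": 99.0,
    "hr_min": 59.0,
    "hr_max": 101.0,
    "pain": 1.1,
    "gcs_min": 13.0,
    "temp_min": 35.9,
    "temp_max": 37.6,
    "haemoglobin": 89.0,
    "k": 3.4,
    "na": 129.0,
    "creatinine": 58.0,
    "bun": 2.4,
}


@pytest.fixture
def boundary_features():
    return dict(BOUNDARY_PASSING)


def make_stay(
    stay_id="s1",
    source="test",
    callout=600,
    discharge=700,
    series=None,
    died=False,
    readmitted=False,
    **kwargs,
):
    """Hand-built stay for unit tests; series values given as python lists."""
    converted = {}
    for var, (t, v) in (series or {}).items():
        converted[var] = (np.asarray(t, dtype=np.int64), np.asarray(v, dtype=float))
    return PatientStay(
        stay_id=stay_id,
        source=source,
        admission_time=0,
        callout_time=callout,
        icu_discharge_time=discharge,
        age=kwargs.get("age", 60.0),
        sex=kwargs.get("sex", 0),
        bmi=kwargs.get("bmi", 25.0),
        died_in_hospital=died,
        readmitted=readmitted,
        series=converted,
    )


def pairwise_auroc_oracle(scores, labels) -> float:
    """Brute-force concordant-pair AUROC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
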