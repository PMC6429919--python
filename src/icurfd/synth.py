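"""Synthetic two-cohort ICU EHR generator.

Each stay gets a per-patient severity and a recovery ramp: every variable
starts displaced from its normal band and relaxes toward the band midpoint
as time approaches callout, with AR(1) bedside noise on top.  Patients whose
ramp stalls short of normal present abnormal physiology at callout, and
outcome flags are drawn from a logistic model on the standardised
callout-time features — a planted ground truth that downstream classifiers
can be tested against.

Two stock configurations ship as generator defaults: a large "mimic-like"
cohort and a smaller "gicu-like" cohort, parameterised by the published
characteristics of the two study populations (size, demographics, length of
stay, discharge delay, mortality/readmission/negative-outcome rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.special import expit

from .features import BASE_FEATURES, extract_features
from .records import LABS, VITALS, PatientStay, band_midpoint

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal

# Admission-time displacement of each variable from its band midpoint
# (signed: the direction in which a deteriorated patient deviates).  A few
# variables carry most of the severity signal; the rest deviate weakly and
# their discharge tests are dominated by measurement noise, so importance
# weighting has something real to exploit.
_DEVIATION: dict[str, float] = {
    "fio2": +0.35,
    "spo2": -2.5,
    "resp": +12.0,
    "bp": -10.0,
    "hr": +32.0,
    "pain": +1.5,
    "gcs": -9.0,
    "temp": +0.5,
    "hco3": -2.5,
    "haemoglobin": -28.0,
    "k": +0.25,
    "na": -3.0,
    "creatinine": +18.0,
    "bun": +7.0,
}

# Stationary SD of the AR(1) measurement noise.
_NOISE_SD: dict[str, float] = {
    "fio2": 0.03,
    "spo2": 1.8,
    "resp": 1.5,
    "bp": 10.0,
    "hr": 5.0,
    "pain": 1.0,
    "gcs": 0.3,
    "temp": 0.45,
    "hco3": 1.5,
    "haemoglobin": 4.0,
    "k": 0.3,
    "na": 2.5,
    "creatinine": 14.0,
    "bun": 0.8,
}

_AR_PHI = 0.7

#: Planted effect sizes (log-odds of a negative outcome per SD of each
#: standardised callout feature).  The coma-score minimum carries the
#: largest magnitude, then airway patency — the structure the importance
#: analyses are expected to recover.
DEFAULT_OUTCOME_COEFFICIENTS: dict[str, float] = {
    "gcs_min": -2.5,
    "airway": -1.5,
    "fio2": 0.9,
    "bun": 0.8,
    "haemoglobin": -0.6,
    "hr_max": 0.4,
    "resp_max": 0.3,
    "hr_min": 0.2,
    "spo2_min": -0.25,
    "hco3": -0.2,
    "na": -0.15,
}

# Per-variable jitter of severity and ramp floor around the patient-level
# latent state.  The coma score and airway are clean readouts of that state;
# everything else is a noisier proxy, which keeps them from substituting for
# gcs/airway in fitted models.
_SEVERITY_JITTER: dict[str, float] = {"gcs": 0.1, "airway": 0.1}
_SEVERITY_JITTER_DEFAULT = 0.6
_FLOOR_JITTER: dict[str, float] = {"gcs": 0.05, "airway": 0.05}
_FLOOR_JITTER_DEFAULT = 0.25


class InvalidConfigError(ValueError):
    """A cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of one synthetic source cohort.

    ``*_median_iqr`` quantities are drawn from a log-normal fitted to the
    given median and interquartile range.  ``negative_outcome_rate`` is the
    target prevalence of death-in-hospital and/or ICU readmission; when
    ``None`` it is derived from the two component rates under independence.
    """

    name: str
    n_patients: int
    frac_female: float = 0.5
    age_median_iqr: tuple[float, tuple[float, float]] = (64.0, (51.0, 77.0))
    bmi_median_iqr: tuple[float, tuple[float, float]] = (28.0, (25.0, 32.0))
    los_median_iqr: tuple[float, tuple[float, float]] = (2.0, (1.1, 3.4))
    discharge_delay_median_iqr: tuple[float, tuple[float, float]] = (0.27, (0.18, 0.39))
    mortality_rate: float = 0.06
    readmission_rate: float = 0.08
    negative_outcome_rate: float | None = None
    vitals_cadence_minutes: float = 60.0
    labs_cadence_hours: float = 12.0
    missingness_rate: float = 0.05
    outcome_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFICIENTS)
    )
    seed: int = 0

    @property
    def target_negative_rate(self) -> float:
        if self.negative_outcome_rate is not None:
            return self.negative_outcome_rate
        m, r = self.mortality_rate, self.readmission_rate
        return 1.0 - (1.0 - m) * (1.0 - r)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be >= 1")
        for nm in ("frac_female", "mortality_rate", "readmission_rate", "missingness_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{nm} must lie in [0, 1], got {v}")
        if self.vitals_cadence_minutes <= 0 or self.labs_cadence_hours <= 0:
            raise InvalidConfigError("sampling cadences must be positive")
        neg = self.target_negative_rate
        if not 0.0 <= neg <= 1.0:
            raise InvalidConfigError("negative_outcome_rate must lie in [0, 1]")
        if neg > 0 and (
            neg < max(self.mortality_rate, self.readmission_rate) - 1e-12
            or neg > self.mortality_rate + self.readmission_rate + 1e-12
        ):
            raise InvalidConfigError(
                "negative_outcome_rate must lie between max and sum of the "
                "mortality and readmission rates"
            )
        unknown = set(self.outcome_coefficients) - set(BASE_FEATURES)
        if unknown:
            raise InvalidConfigError(f"outcome coefficients for unknown features: {sorted(unknown)}")

    def with_overrides(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def mimic_like(**overrides) -> CohortConfig:
    """Defaults emulating the large US medical/surgical ICU cohort."""
    cfg = CohortConfig(
        name="mimic-like",
        n_patients=7592,
        frac_female=0.476,
        age_median_iqr=(64.0, (50.9, 77.0)),
        bmi_median_iqr=(28.1, (24.9, 31.6)),
        los_median_iqr=(1.93, (1.11, 3.34)),
        discharge_delay_median_iqr=(0.27, (0.18, 0.39)),
        mortality_rate=0.0614,
        readmission_rate=0.0776,
        negative_outcome_rate=0.1257,
        seed=0,
    )
    return cfg.with_overrides(**overrides)


def gicu_like(**overrides) -> CohortConfig:
    """Defaults emulating the smaller UK general ICU cohort."""
    cfg = CohortConfig(
        name="gicu-like",
        n_patients=1870,
        frac_female=0.405,
        age_median_iqr=(63.0, (49.0, 72.8)),
        bmi_median_iqr=(26.5, (22.8, 30.6)),
        los_median_iqr=(2.96, (1.69, 5.14)),
        discharge_delay_median_iqr=(0.34, (0.20, 1.04)),
        mortality_rate=0.0358,
        readmission_rate=0.0278,
        negative_outcome_rate=0.0583,
        seed=1,
    )
    return cfg.with_overrides(**overrides)


def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    q1, q3 = iqr
    if not (0 < q1 < q3) or median <= 0:
        raise InvalidConfigError(f"median/IQR must be positive with q1 < q3, got {median}, {iqr}")
    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2.0 * _Z75)
    return mu, sigma


def _sample_grid(rng: np.random.Generator, t_end: int, cadence_min: float) -> np.ndarray:
    """Jittered near-regular sampling grid over [0, t_end], integer minutes."""
    n = int(t_end // cadence_min) + 1
    base = np.arange(n) * cadence_min
    jitter = rng.normal(0.0, 0.1 * cadence_min, size=n)
    t = np.clip(np.round(base + jitter), 0, t_end).astype(np.int64)
    return np.unique(t)


def _ar1(rng: np.random.Generator, shape: tuple[int, int], sds: np.ndarray) -> np.ndarray:
    eps = rng.standard_normal(shape) * (sds * np.sqrt(1.0 - _AR_PHI**2))
    return lfilter([1.0], [1.0, -_AR_PHI], eps, axis=0)


def _simulate_block(
    rng: np.random.Generator,
    variables: list[str],
    t: np.ndarray,
    callout: int,
    severity: float,
    ramp_floor: float,
) -> np.ndarray:
    """Value matrix (len(t) x len(variables)); airway handled separately."""
    progress = np.minimum(t / max(callout, 1), 1.0)
    sev = np.array(
        [
            severity
            * np.exp(rng.normal(0.0, _SEVERITY_JITTER.get(v, _SEVERITY_JITTER_DEFAULT)))
            for v in variables
        ]
    )
    floor = np.array(
        [
            np.clip(
                ramp_floor + rng.normal(0.0, _FLOOR_JITTER.get(v, _FLOOR_JITTER_DEFAULT)),
                0.0,
                0.9,
            )
            for v in variables
        ]
    )
    # 1 at admission -> per-variable floor at callout
    g = 1.0 - progress[:, None] * (1.0 - floor[None, :])
    cols = [i for i, v in enumerate(variables) if v != "airway"]
    sds = np.array([_NOISE_SD[variables[i]] for i in cols])
    noise = _ar1(rng, (len(t), len(cols)), sds)
    mids = np.array([band_midpoint(variables[i]) for i in cols])
    devs = np.array([_DEVIATION[variables[i]] for i in cols])
    vals = mids + devs * sev[cols] * g[:, cols] + noise
    out = np.empty((len(t), len(variables)))
    j = 0
    for i, v in enumerate(variables):
        if v == "airway":
            p_obstructed = np.clip(0.95 * g[:, i] ** 1.5 * min(sev[i], 1.2), 0.0, 0.98)
            out[:, i] = (rng.random(len(t)) >= p_obstructed).astype(float)
        else:
            out[:, i] = vals[:, j]
            j += 1
    # physiological clipping / integer coding
    for i, v in enumerate(variables):
        if v == "fio2":
            out[:, i] = np.clip(out[:, i], 0.21, 1.0)
        elif v == "spo2":
            out[:, i] = np.clip(out[:, i], 0.0, 100.0)
        elif v == "gcs":
            out[:, i] = np.clip(np.round(out[:, i]), 3, 15)
        elif v == "pain":
            out[:, i] = np.clip(np.round(out[:, i]), 0, 10)
        elif v == "resp":
            out[:, i] = np.clip(out[:, i], 0.0, 70.0)
        elif v == "hr":
            out[:, i] = np.clip(out[:, i], 20.0, 220.0)
        elif v == "bp":
            out[:, i] = np.clip(out[:, i], 40.0, 260.0)
        elif v == "temp":
            out[:, i] = np.clip(out[:, i], 33.0, 42.0)
        elif v == "k":
            out[:, i] = np.clip(out[:, i], 1.5, 9.0)
        elif v == "creatinine":
            out[:, i] = np.clip(out[:, i], 20.0, 1000.0)
        elif v in ("hco3", "haemoglobin", "na", "bun"):
            out[:, i] = np.maximum(out[:, i], 0.5)
    return out


def generate_cohort(config: CohortConfig) -> list[PatientStay]:
    """Generate ``config.n_patients`` stays; identical seed, identical output.

    Physiology is simulated first; outcome flags are then drawn from the
    planted logistic model on standardised callout-time features, with the
    intercept calibrated so the cohort mean matches the configured
    negative-outcome rate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    age_mu, age_sg = _lognormal_params(*config.age_median_iqr)
    bmi_mu, bmi_sg = _lognormal_params(*config.bmi_median_iqr)
    los_mu, los_sg = _lognormal_params(*config.los_median_iqr)
    dly_mu, dly_sg = _lognormal_params(*config.discharge_delay_median_iqr)

    stays: list[PatientStay] = []
    for i in range(n):
        sex = int(rng.random() < config.frac_female)
        age = float(np.clip(rng.lognormal(age_mu, age_sg), 18.0, 100.0))
        bmi = float(np.clip(rng.lognormal(bmi_mu, bmi_sg), 12.0, 70.0))
        los_days = max(rng.lognormal(los_mu, los_sg), 0.15)
        delay_days = rng.lognormal(dly_mu, dly_sg)
        delay_days = min(delay_days, 0.5 * los_days)
        discharge = int(round(los_days * 1440))
        callout = max(discharge - int(round(delay_days * 1440)), 60)

        severity = float(rng.lognormal(0.0, 0.35))
        ramp_floor = float(np.clip(rng.normal(0.06, 0.20), 0.0, 0.85))

        series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tv = _sample_grid(rng, discharge, config.vitals_cadence_minutes)
        vit = _simulate_block(rng, VITALS, tv, callout, severity, ramp_floor)
        tl = _sample_grid(rng, discharge, config.labs_cadence_hours * 60.0)
        lab = _simulate_block(rng, LABS, tl, callout, severity, ramp_floor)
        for block_t, block_v, names in ((tv, vit, VITALS), (tl, lab, LABS)):
            keep_matrix = rng.random(block_v.shape) >= config.missingness_rate
            for j, var in enumerate(names):
                keep = keep_matrix[:, j]
                if keep.any():
                    series[var] = (block_t[keep], block_v[keep, j])

        stays.append(
            PatientStay(
                stay_id=f"{config.name}-{i:05d}",
                source=config.name,
                admission_time=0,
                callout_time=callout,
                icu_discharge_time=discharge,
                age=age,
                sex=sex,
                bmi=bmi,
                died_in_hospital=False,
                readmitted=False,
                series=series,
            )
        )

    _assign_outcomes(rng, stays, config)
    return stays


def _assign_outcomes(rng: np.random.Generator, stays: list[PatientStay], config: CohortConfig) -> None:
    target = config.target_negative_rate
    if target <= 0.0:
        return
    X = np.vstack(
        [extract_features(s, s.callout_time).as_array(BASE_FEATURES) for s in stays]
    )
    obs = ~np.isnan(X)
    counts = obs.sum(axis=0)
    col_mean = np.where(obs, X, 0.0).sum(axis=0) / np.maximum(counts, 1)
    inds = np.where(~obs)
    X[inds] = np.take(col_mean, inds[1])
    sd = X.std(axis=0)
    Z = np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    coef = np.array([config.outcome_coefficients.get(f, 0.0) for f in BASE_FEATURES])
    lp = Z @ coef

    if target >= 1.0:
        p = np.ones(len(stays))
    else:

        def excess(b: float) -> float:
            return float(expit(b + lp).mean() - target)

        intercept = brentq(excess, -40.0, 40.0)
        p = expit(intercept + lp)

    negative = rng.random(len(stays)) < p

    m, r = config.mortality_rate, config.readmission_rate
    p_both = max(m + r - target, 0.0) / target
    p_died_only = max(target - r, 0.0) / target
    p_readm_only = max(target - m, 0.0) / target
    tot = p_both + p_died_only + p_readm_only
    probs = np.array([p_both, p_died_only, p_readm_only]) / tot
    for s, neg in zip(stays, negative):
        if not neg:
            continue
        kind = rng.choice(3, p=probs)
        s.died_in_hospital = kind in (0, 1)
        s.readmitted = kind in (0, 2)
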