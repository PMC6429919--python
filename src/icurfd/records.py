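"""Core record types and the clinical variable registry.

A stay's time series are stored per variable as parallel arrays of integer
minutes since admission and float values.  Fifteen variables are tracked:
the nine vital signs charted frequently at the bedside and the six
laboratory analytes measured a few times a day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Vital signs: sampled on the bedside-chart cadence (default hourly).
VITALS = ["airway", "fio2", "spo2", "resp", "bp", "hr", "pain", "gcs", "temp"]

#: Laboratory analytes: sampled sparsely (default every 12 h).
LABS = ["hco3", "haemoglobin", "k", "na", "creatinine", "bun"]

#: All tracked clinical variables, in canonical order.
VARIABLES = VITALS + LABS

#: Per-variable "normal" band (lower, upper).  The band edges coincide with
#: the codified discharge-test bounds where those are two-sided; one-sided
#: tests get a physiologically sensible closing edge.  Used by the generator
#: as the recovery target and by trajectory diagnostics as the reference
#: midpoint.
NORMAL_BANDS: dict[str, tuple[float, float]] = {
    "airway": (1.0, 1.0),
    "fio2": (0.21, 0.6),
    "spo2": (95.0, 100.0),
    "resp": (10.0, 30.0),
    "bp": (100.0, 140.0),
    "hr": (60.0, 100.0),
    "pain": (0.0, 1.0),
    "gcs": (14.0, 15.0),
    "temp": (36.0, 37.5),
    "hco3": (19.0, 29.0),
    "haemoglobin": (90.0, 160.0),
    "k": (3.5, 6.0),
    "na": (130.0, 150.0),
    "creatinine": (59.0, 104.0),
    "bun": (2.5, 7.8),
}


def band_midpoint(variable: str) -> float:
    lo, hi = NORMAL_BANDS[variable]
    return 0.5 * (lo + hi)


class StayValidationError(ValueError):
    """A stay violates one of its structural invariants."""


@dataclass(eq=False)
class PatientStay:
    """One ICU stay: event times, demographics, outcomes, and time series.

    All timestamps are integer minutes since admission, so
    ``admission_time`` is always 0 for generated stays.  ``series`` maps a
    variable name to ``(times, values)`` arrays sorted by time; variables
    with no observations are simply absent from the mapping.
    """

    stay_id: str
    source: str
    admission_time: int
    callout_time: int
    icu_discharge_time: int
    age: float
    sex: int  # 1 = female, 0 = male
    bmi: float
    died_in_hospital: bool
    readmitted: bool
    series: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def has_variable(self, variable: str) -> bool:
        return variable in self.series and len(self.series[variable][0]) > 0

    @property
    def negative_outcome(self) -> bool:
        return bool(self.died_in_hospital or self.readmitted)

    def validate(self) -> None:
        if not self.admission_time < self.callout_time <= self.icu_discharge_time:
            raise StayValidationError(
                f"stay {self.stay_id}: require admission < callout <= discharge, "
                f"got {self.admission_time}, {self.callout_time}, "
                f"{self.icu_discharge_time}"
            )
        for var, (t, v) in self.series.items():
            if var not in NORMAL_BANDS:
                raise StayValidationError(f"stay {self.stay_id}: unknown variable {var!r}")
            if len(t) != len(v):
                raise StayValidationError(
                    f"stay {self.stay_id}/{var}: times and values length mismatch"
                )
            if len(t) == 0:
                continue
            if t[0] < self.admission_time or t[-1] > self.icu_discharge_time:
                raise StayValidationError(
                    f"stay {self.stay_id}/{var}: timestamps outside stay interval"
                )
            if np.any(np.diff(t) < 0):
                raise StayValidationError(f"stay {self.stay_id}/{var}: times not sorted")
            if var == "gcs":
                if np.any(v != np.round(v)) or np.any(v < 3) or np.any(v > 15):
                    raise StayValidationError(
                        f"stay {self.stay_id}: gcs must be integer in [3, 15]"
                    )
            elif var == "fio2":
                if np.any(v < 0.21) or np.any(v > 1.0):
                    raise StayValidationError(
                        f"stay {self.stay_id}: fio2 must lie in [0.21, 1.0]"
                    )
            elif var == "spo2":
                if np.any(v < 0) or np.any(v > 100):
                    raise StayValidationError(
                        f"stay {self.stay_id}: spo2 must lie in [0, 100]"
                    )
            elif var == "pain":
                if np.any(v != np.round(v)) or np.any(v < 0) or np.any(v > 10):
                    raise StayValidationError(
                        f"stay {self.stay_id}: pain must be integer in [0, 10]"
                    )
            elif var == "airway":
                if not np.all(np.isin(v, (0.0, 1.0))):
                    raise StayValidationError(
                        f"stay {self.stay_id}: airway must be binary (1 = patent)"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientStay):
            return NotImplemented
        scalar = (
            self.stay_id == other.stay_id
            and self.source == other.source
            and self.admission_time == other.admission_time
            and self.callout_time == other.callout_time
            and self.icu_discharge_time == other.icu_discharge_time
            and self.age == other.age
            and self.sex == other.sex
            and self.bmi == other.bmi
            and self.died_in_hospital == other.died_in_hospital
            and self.readmitted == other.readmitted
        )
        if not scalar:
            return False
        mine = {k for k, (t, _) in self.series.items() if len(t)}
        theirs = {k for k, (t, _) in other.series.items() if len(t)}
        if mine != theirs:
            return False
        for var in mine:
            t1, v1 = self.series[var]
            t2, v2 = other.series[var]
            if not (np.array_equal(t1, t2) and np.array_equal(v1, v2)):
                return False
        return True
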