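"""The 15 codified nurse-led discharge (NLD) tests and derived scores.

Each test is an inclusive threshold condition on one or two extracted
features.  Tests with two features (respiratory rate, heart rate,
temperature) pass when the window minimum respects the lower bound and the
window maximum respects the upper bound.  A test whose inputs are missing
fails and is flagged — the conservative policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .features import BASE_FEATURES, FeatureVector, extract_features
from .records import PatientStay


class InvalidThresholdError(ValueError):
    pass


class InvalidWeightsError(ValueError):
    pass


@dataclass(frozen=True)
class TestSpec:
    """One codified discharge test: inclusive bounds on feature(s).

    ``features`` holds one name for single-feature tests, or
    ``(min_feature, max_feature)`` for two-feature tests.  ``None`` bounds
    are one-sided.
    """

    test_id: str
    name: str
    features: tuple[str, ...]
    lower: float | None
    upper: float | None
    units: str = ""

    def evaluate(self, fv: FeatureVector | Mapping[str, float]) -> tuple[bool, bool]:
        """Return (passed, had_missing_input)."""
        vals = []
        for f in self.features:
            v = fv[f] if f in fv else math.nan
            if v != v:  # NaN
                return False, True
            vals.append(v)
        if len(vals) == 1:
            v = vals[0]
            ok = (self.lower is None or v >= self.lower) and (
                self.upper is None or v <= self.upper
            )
        else:
            vmin, vmax = vals
            ok = vmin >= self.lower and vmax <= self.upper
        return bool(ok), False


_DEFAULT_SPECS = [
    TestSpec("R0", "Respiratory: airway", ("airway",), 1.0, None, ""),
    TestSpec("R1", "Respiratory: FiO2", ("fio2",), None, 0.6, ""),
    TestSpec("R2", "Respiratory: blood oxygen", ("spo2_min",), 95.0, None, "%"),
    TestSpec("R3", "Respiratory: bicarbonate", ("hco3",), 19.0, None, "mmol/L"),
    TestSpec("R4", "Respiratory: rate", ("resp_min", "resp_max"), 10.0, 30.0, "bpm"),
    TestSpec("C0", "Cardiovascular: blood pressure", ("bp_min",), 100.0, None, "mm Hg"),
    TestSpec("C1", "Cardiovascular: heart rate", ("hr_min", "hr_max"), 60.0, 100.0, "bpm"),
    TestSpec("P", "Pain", ("pain",), 0.0, 1.0, ""),
    TestSpec("CNS", "Central nervous system", ("gcs_min",), 14.0, None, ""),
    TestSpec("T", "Temperature", ("temp_min", "temp_max"), 36.0, 37.5, "degC"),
    TestSpec("B0", "Bloods: haemoglobin", ("haemoglobin",), 90.0, None, "g/L"),
    TestSpec("B1", "Bloods: potassium", ("k",), 3.5, 6.0, "mmol/L"),
    TestSpec("B2", "Bloods: sodium", ("na",), 130.0, 150.0, "mmol/L"),
    TestSpec("B3", "Bloods: creatinine", ("creatinine",), 59.0, 104.0, "umol/L"),
    TestSpec("B4", "Bloods: urea", ("bun",), 2.5, 7.8, "mmol/L"),
]

TEST_IDS = [s.test_id for s in _DEFAULT_SPECS]
N_TESTS = len(TEST_IDS)


@dataclass
class CriteriaThresholds:
    """The full 15-test rule set; bounds are overridable defaults."""

    tests: dict[str, TestSpec] = field(
        default_factory=lambda: {s.test_id: s for s in _DEFAULT_SPECS}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if sorted(self.tests) != sorted(TEST_IDS):
            raise InvalidThresholdError(
                f"expected exactly the {N_TESTS} tests {TEST_IDS}, got {sorted(self.tests)}"
            )
        for spec in self.tests.values():
            if spec.lower is None and spec.upper is None:
                raise InvalidThresholdError(f"test {spec.test_id}: no bounds")
            if spec.lower is not None and spec.upper is not None and not spec.lower < spec.upper:
                raise InvalidThresholdError(
                    f"test {spec.test_id}: lower bound {spec.lower} must be "
                    f"strictly below upper bound {spec.upper}"
                )

    def override(self, test_id: str, lower: float | None = ..., upper: float | None = ...) -> "CriteriaThresholds":
        spec = self.tests[test_id]
        new = TestSpec(
            spec.test_id,
            spec.name,
            spec.features,
            spec.lower if lower is ... else lower,
            spec.upper if upper is ... else upper,
            spec.units,
        )
        tests = dict(self.tests)
        tests[test_id] = new
        return CriteriaThresholds(tests)

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {
                "test_id": s.test_id,
                "name": s.name,
                "features": list(s.features),
                "lower": s.lower,
                "upper": s.upper,
                "units": s.units,
            }
            for s in (self.tests[tid] for tid in TEST_IDS)
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CriteriaThresholds":
        data = yaml.safe_load(Path(path).read_text())
        tests = {
            d["test_id"]: TestSpec(
                d["test_id"],
                d.get("name", d["test_id"]),
                tuple(d["features"]),
                d.get("lower"),
                d.get("upper"),
                d.get("units", ""),
            )
            for d in data
        }
        return cls(tests)


@dataclass
class CriteriaResult:
    """Pass/fail status of the 15 tests for one instance."""

    passed: dict[str, bool]
    tests_with_missing_inputs: frozenset[str] = frozenset()

    @property
    def n_passed(self) -> int:
        return sum(self.passed.values())

    @property
    def all_passed(self) -> bool:
        return self.n_passed == N_TESTS


def evaluate_tests(
    fv: FeatureVector | Mapping[str, float],
    thresholds: CriteriaThresholds | None = None,
) -> CriteriaResult:
    """Evaluate all 15 tests on a feature vector (missing inputs fail)."""
    thresholds = thresholds or CriteriaThresholds()
    passed: dict[str, bool] = {}
    missing: set[str] = set()
    for tid in TEST_IDS:
        ok, had_missing = thresholds.tests[tid].evaluate(fv)
        passed[tid] = ok
        if had_missing:
            missing.add(tid)
    return CriteriaResult(passed, frozenset(missing))


def nld_score(result: CriteriaResult) -> float:
    """Normalised criteria score: tests passed divided by 15."""
    return result.n_passed / N_TESTS


@dataclass
class CriteriaWeights:
    """Non-negative per-test weights, normalised to sum to one."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if sorted(self.weights) != sorted(TEST_IDS):
            raise InvalidWeightsError("weights must cover exactly the 15 test IDs")
        vals = np.array([self.weights[t] for t in TEST_IDS], dtype=float)
        if (vals < 0).any():
            bad = TEST_IDS[int(np.flatnonzero(vals < 0)[0])]
            raise InvalidWeightsError(f"negative weight for test {bad}")
        total = vals.sum()
        if total <= 0:
            raise InvalidWeightsError("weights sum to zero")
        self.weights = {t: float(self.weights[t] / total) for t in TEST_IDS}

    @classmethod
    def uniform(cls) -> "CriteriaWeights":
        return cls({t: 1.0 for t in TEST_IDS})


def weighted_score(result: CriteriaResult, weights: CriteriaWeights) -> float:
    """Importance-weighted criteria score: sum of weights of passed tests."""
    return float(sum(weights.weights[t] for t in TEST_IDS if result.passed[t]))


def weights_from_importance(
    importances: Mapping[str, float],
    thresholds: CriteriaThresholds | None = None,
) -> CriteriaWeights:
    """Map per-feature importances to per-test weights.

    Each test's raw weight is the sum of the non-negative (floored at zero)
    importances of its constituent features; weights are then normalised.
    If every importance floors to zero, uniform weights are returned.
    """
    thresholds = thresholds or CriteriaThresholds()
    for f in BASE_FEATURES:
        if f not in importances:
            raise InvalidWeightsError(f"missing importance for feature {f!r}")
    raw = {}
    for tid in TEST_IDS:
        spec = thresholds.tests[tid]
        raw[tid] = sum(max(float(importances[f]), 0.0) for f in spec.features)
    if sum(raw.values()) <= 0:
        return CriteriaWeights.uniform()
    return CriteriaWeights(raw)


@dataclass
class SustainedResult:
    """Outcome of the sustained all-criteria discharge rule."""

    ok: bool
    checked_times: list[int]
    failed_at: int | None = None
    failure: CriteriaResult | None = None

    def __bool__(self) -> bool:
        return self.ok


def sustained_rfd(
    stay: PatientStay,
    at_time: float,
    window_hours: float = 4.0,
    thresholds: CriteriaThresholds | None = None,
) -> SustainedResult:
    """All 15 tests must hold at every observation grid point in the
    trailing ``window_hours`` before ``at_time`` (and at ``at_time`` itself).

    Raises ``ValueError`` when ``at_time`` lies outside the stay.
    """
    if not stay.admission_time <= at_time <= stay.icu_discharge_time:
        raise ValueError(
            f"at_time {at_time} outside stay [{stay.admission_time}, "
            f"{stay.icu_discharge_time}]"
        )
    thresholds = thresholds or CriteriaThresholds()
    lo = at_time - window_hours * 60.0
    grid: set[int] = {int(at_time)}
    for times, _ in stay.series.values():
        sel = times[(times > lo) & (times <= at_time)]
        grid.update(int(t) for t in sel)
    checked = sorted(grid)
    for t in checked:
        result = evaluate_tests(extract_features(stay, t), thresholds)
        if not result.all_passed:
            return SustainedResult(False, checked, failed_at=t, failure=result)
    return SustainedResult(True, checked)
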