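import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icurfd.criteria import (
    N_TESTS,
    TEST_IDS,
    CriteriaResult,
    CriteriaThresholds,
    CriteriaWeights,
    InvalidThresholdError,
    InvalidWeightsError,
    evaluate_tests,
    nld_score,
    sustained_rfd,
    weighted_score,
    weights_from_importance,
)
from icurfd.features import BASE_FEATURES

from conftest import BOUNDARY_VIOLATIONS, make_stay


def result_from_pattern(bits):
    return CriteriaResult({tid: bool(b) for tid, b in zip(TEST_IDS, bits)})


class TestThresholds:
    def test_exactly_15_tests(self):
        assert len(CriteriaThresholds().tests) == 15

    def test_default_bounds_match_printed_table(self):
        t = CriteriaThresholds().tests
        assert t["R1"].upper == 0.6 and t["R1"].lower is None
        assert t["R2"].lower == 95.0
        assert t["R3"].lower == 19.0
        assert (t["R4"].lower, t["R4"].upper) == (10.0, 30.0)
        assert t["C0"].lower == 100.0
        assert (t["C1"].lower, t["C1"].upper) == (60.0, 100.0)
        assert (t["P"].lower, t["P"].upper) == (0.0, 1.0)
        assert t["CNS"].lower == 14.0
        assert (t["T"].lower, t["T"].upper) == (36.0, 37.5)
        assert t["B0"].lower == 90.0
        assert (t["B1"].lower, t["B1"].upper) == (3.5, 6.0)
        assert (t["B2"].lower, t["B2"].upper) == (130.0, 150.0)
        assert (t["B3"].lower, t["B3"].upper) == (59.0, 104.0)
        assert (t["B4"].lower, t["B4"].upper) == (2.5, 7.8)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(InvalidThresholdError):
            CriteriaThresholds().override("B4", lower=8.0, upper=2.5)

    def test_override_is_functional(self):
        base = CriteriaThresholds()
        changed = base.override("CNS", lower=15.0)
        assert changed.tests["CNS"].lower == 15.0
        assert base.tests["CNS"].lower == 14.0

    def test_yaml_round_trip(self, tmp_path):
        th = CriteriaThresholds().override("B1", lower=3.0)
        path = tmp_path / "thresholds.yaml"
        th.to_yaml(path)
        again = CriteriaThresholds.from_yaml(path)
        assert again.tests == th.tests


class TestEvaluateTests:
    def test_gcs_boundary(self, boundary_features):
        boundary_features["gcs_min"] = 14
        assert evaluate_tests(boundary_features).passed["CNS"]
        boundary_features["gcs_min"] = 13
        assert not evaluate_tests(boundary_features).passed["CNS"]

    def test_fio2_inclusive_upper(self, boundary_features):
        boundary_features["fio2"] = 0.6
        assert evaluate_tests(boundary_features).passed["R1"]

    def test_heart_rate_lower_bound_violation(self, boundary_features):
        boundary_features["hr_min"] = 59
        boundary_features["hr_max"] = 100
        assert not evaluate_tests(boundary_features).passed["C1"]

    def test_all_boundary_values_pass(self, boundary_features):
        result = evaluate_tests(boundary_features)
        assert result.n_passed == 15
        assert result.tests_with_missing_inputs == frozenset()

    @pytest.mark.parametrize("feature", sorted(BOUNDARY_VIOLATIONS))
    def test_single_perturbation_drops_exactly_one(self, boundary_features, feature):
        boundary_features[feature] = BOUNDARY_VIOLATIONS[feature]
        assert evaluate_tests(boundary_features).n_passed == 14

    def test_missing_input_fails_and_is_recorded(self, boundary_features):
        boundary_features["bun"] = math.nan
        result = evaluate_tests(boundary_features)
        assert not result.passed["B4"]
        assert result.tests_with_missing_inputs == frozenset({"B4"})

    def test_missing_in_paired_test(self, boundary_features):
        boundary_features["hr_max"] = math.nan
        result = evaluate_tests(boundary_features)
        assert not result.passed["C1"]
        assert "C1" in result.tests_with_missing_inputs


class TestScores:
    def test_extremes_and_nine(self):
        assert nld_score(result_from_pattern([1] * 15)) == 1.0
        assert nld_score(result_from_pattern([0] * 15)) == 0.0
        assert nld_score(result_from_pattern([1] * 9 + [0] * 6)) == pytest.approx(0.6)

    def test_score_values_are_sixteenths_of_fifteen(self):
        values = {nld_score(result_from_pattern([1] * k + [0] * (15 - k))) for k in range(16)}
        assert values == {k / 15 for k in range(16)}

    def test_threshold_family_counts_at_least_k(self):
        # thresholding the score at k/15 recovers "at least k tests passed"
        rng = np.random.default_rng(0)
        patterns = rng.integers(0, 2, size=(64, 15))
        scores = np.array([nld_score(result_from_pattern(p)) for p in patterns])
        for k in range(16):
            assert np.sum(scores >= k / 15 - 1e-12) == np.sum(patterns.sum(axis=1) >= k)

    def test_weighted_uniform_equals_nld(self):
        w = CriteriaWeights.uniform()
        rng = np.random.default_rng(1)
        for p in rng.integers(0, 2, size=(50, 15)):
            r = result_from_pattern(p)
            assert weighted_score(r, w) == pytest.approx(nld_score(r))

    def test_degenerate_weight_on_cns(self):
        w = CriteriaWeights({t: (1.0 if t == "CNS" else 0.0) for t in TEST_IDS})
        r = result_from_pattern([tid == "CNS" for tid in TEST_IDS])
        assert weighted_score(r, w) == 1.0

    def test_half_weights(self):
        w = CriteriaWeights({t: (0.5 if t in ("CNS", "R0") else 0.0) for t in TEST_IDS})
        r = result_from_pattern([tid == "CNS" for tid in TEST_IDS])
        assert weighted_score(r, w) == pytest.approx(0.5)

    def test_negative_weight_rejected(self):
        bad = {t: 1.0 for t in TEST_IDS}
        bad["P"] = -0.1
        with pytest.raises(InvalidWeightsError):
            CriteriaWeights(bad)

    @given(st.lists(st.booleans(), min_size=15, max_size=15))
    @settings(max_examples=200, deadline=None)
    def test_uniform_weight_identity_property(self, bits):
        r = result_from_pattern(bits)
        assert weighted_score(r, CriteriaWeights.uniform()) == pytest.approx(nld_score(r))

    @given(
        st.lists(st.booleans(), min_size=15, max_size=15),
        st.integers(min_value=0, max_value=14),
        st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=15, max_size=15),
    )
    @settings(max_examples=200, deadline=None)
    def test_flipping_fail_to_pass_never_decreases(self, bits, idx, raw_w):
        if sum(raw_w) <= 0:
            raw_w = [1.0] * 15
        w = CriteriaWeights(dict(zip(TEST_IDS, raw_w)))
        lo = list(bits)
        lo[idx] = False
        hi = list(bits)
        hi[idx] = True
        r_lo, r_hi = result_from_pattern(lo), result_from_pattern(hi)
        assert nld_score(r_hi) >= nld_score(r_lo)
        assert weighted_score(r_hi, w) >= weighted_score(r_lo, w) - 1e-12


class TestWeightsFromImportance:
    def test_uniform_importances_give_uniform_weights(self):
        imp = {f: 1.0 for f in BASE_FEATURES}
        w = weights_from_importance(imp)
        for t in TEST_IDS:
            # two-feature tests aggregate two uniform importances
            n_feats = len(CriteriaThresholds().tests[t].features)
            assert w.weights[t] == pytest.approx(n_feats / 18)

    def test_concentrated_on_gcs_maps_to_cns(self):
        imp = {f: 0.0 for f in BASE_FEATURES}
        imp["gcs_min"] = 3.0
        w = weights_from_importance(imp)
        assert w.weights["CNS"] == pytest.approx(1.0)

    def test_heart_rate_pair_aggregation(self):
        # hand computation: C1 weight = (imp[hr_min] + imp[hr_max]) / total
        imp = {f: 0.1 for f in BASE_FEATURES}
        imp["hr_min"], imp["hr_max"] = 0.4, 0.6
        total = 0.1 * 16 + 0.4 + 0.6
        w = weights_from_importance(imp)
        assert w.weights["C1"] == pytest.approx((0.4 + 0.6) / total)

    def test_negative_importances_floored(self):
        imp = {f: 0.0 for f in BASE_FEATURES}
        imp["gcs_min"] = 1.0
        imp["bun"] = -5.0
        w = weights_from_importance(imp)
        assert w.weights["B4"] == 0.0
        assert w.weights["CNS"] == pytest.approx(1.0)

    def test_missing_feature_named_in_error(self):
        imp = {f: 1.0 for f in BASE_FEATURES if f != "creatinine"}
        with pytest.raises(InvalidWeightsError, match="creatinine"):
            weights_from_importance(imp)


def _steady_series(value, t_end=600, step=60):
    t = list(range(0, t_end + 1, step))
    return (t, [value] * len(t))


def _normal_stay(**series_overrides):
    series = {
        "airway": _steady_series(1.0),
        "fio2": _steady_series(0.3),
        "spo2": _steady_series(98.0),
        "resp": _steady_series(15.0),
        "bp": _steady_series(120.0),
        "hr": _steady_series(75.0),
        "pain": _steady_series(0.0),
        "gcs": _steady_series(15.0),
        "temp": _steady_series(36.8),
        "hco3": _steady_series(24.0),
        "haemoglobin": _steady_series(120.0),
        "k": _steady_series(4.2),
        "na": _steady_series(140.0),
        "creatinine": _steady_series(80.0),
        "bun": _steady_series(5.0),
    }
    series.update(series_overrides)
    return make_stay(callout=600, discharge=700, series=series)


class TestSustainedRfd:
    def test_all_in_range_for_six_hours(self):
        assert sustained_rfd(_normal_stay(), at_time=360)

    def test_violation_one_hour_before_fails(self):
        hr = ([0, 60, 120, 180, 240, 300, 360], [75, 75, 75, 75, 75, 130, 75])
        res = sustained_rfd(_normal_stay(hr=hr), at_time=360)
        assert not res
        assert res.failed_at == 300
        assert not res.failure.passed["C1"]

    def test_missing_inputs_fail_and_are_flagged(self):
        # no potassium anywhere: B1 has no data even with the 36 h fallback
        stay = _normal_stay()
        del stay.series["k"]
        res = sustained_rfd(stay, at_time=360)
        assert not res
        assert "B1" in res.failure.tests_with_missing_inputs

    def test_at_time_outside_stay_raises(self):
        with pytest.raises(ValueError):
            sustained_rfd(_normal_stay(), at_time=9999)
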