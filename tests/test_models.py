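import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from icurfd.metrics import auroc
from icurfd.models import (
    ModelFamily,
    SplitSpec,
    fit_final,
    forest_family,
    logistic_family,
    multisource_split,
    permutation_importance,
    run_experiment,
    tune_multisource_cv,
)


def _toy_dataset(n_gicu=100, n_mimic=400, seed=0):
    rng = np.random.default_rng(seed)
    n = n_gicu + n_mimic
    x = rng.normal(size=n)
    y = np.where(x + 0.5 * rng.normal(size=n) > 0, "RFD", "NRFD")
    return pd.DataFrame(
        {
            "source": ["gicu-like"] * n_gicu + ["mimic-like"] * n_mimic,
            "label": y,
            "f1": x,
            "f2": rng.normal(size=n),
        }
    )


SPEC = SplitSpec(fraction_source="gicu-like", matched_source="mimic-like")


class TestMultisourceSplit:
    def test_thirty_percent_and_equal_size(self):
        df = _toy_dataset(100, 400)
        train, tests = multisource_split(df, SPEC, np.random.default_rng(0))
        assert len(tests["gicu-like"]) == 30
        assert len(tests["mimic-like"]) == 30
        assert len(train) == 440

    def test_rounding_small_cohort(self):
        df = _toy_dataset(10, 50)
        train, tests = multisource_split(df, SPEC, np.random.default_rng(0))
        assert len(tests["gicu-like"]) == 3
        assert len(tests["mimic-like"]) == 3

    def test_single_source_raises(self):
        df = _toy_dataset(0, 50)
        with pytest.raises(ValueError):
            multisource_split(df, SPEC, np.random.default_rng(0))

    def test_matched_source_too_small_raises(self):
        df = _toy_dataset(100, 20)
        with pytest.raises(ValueError):
            multisource_split(df, SPEC, np.random.default_rng(0))

    def test_disjoint_and_source_pure(self):
        df = _toy_dataset(60, 200)
        train, tests = multisource_split(df, SPEC, np.random.default_rng(1))
        test_idx = set(tests["gicu-like"].index) | set(tests["mimic-like"].index)
        assert test_idx.isdisjoint(set(train.index))
        assert set(tests["gicu-like"]["source"]) == {"gicu-like"}
        assert set(tests["mimic-like"]["source"]) == {"mimic-like"}
        assert set(train["source"]) == {"gicu-like", "mimic-like"}


class TestTuning:
    def test_grid_of_size_one(self):
        df = _toy_dataset()
        fam = logistic_family(cs=[1.0])
        X = df[["f1", "f2"]].to_numpy()
        y = (df["label"] == "RFD").to_numpy(dtype=int)
        params, scores = tune_multisource_cv(X, y, df["source"].to_numpy(), fam)
        assert params == {"C": 1.0}
        assert len(scores) == 1

    def test_constant_model_never_selected(self):
        from sklearn.dummy import DummyClassifier

        def build(params, seed):
            if params["kind"] == "constant":
                return DummyClassifier(strategy="prior")
            return LogisticRegression(max_iter=500)

        fam = ModelFamily("mix", build, [{"kind": "constant"}, {"kind": "logistic"}])
        df = _toy_dataset()
        X = df[["f1", "f2"]].to_numpy()
        y = (df["label"] == "RFD").to_numpy(dtype=int)
        params, scores = tune_multisource_cv(X, y, df["source"].to_numpy(), fam)
        assert params == {"kind": "logistic"}
        assert scores[0] == pytest.approx(0.5)  # constant scorer: AUROC 1/2

    def test_selected_point_beats_all_others(self):
        # exhaustive oracle over the returned per-point scores
        df = _toy_dataset(seed=3)
        fam = logistic_family(cs=[1e-4, 1e-2, 1.0, 100.0])
        X = df[["f1", "f2"]].to_numpy()
        y = (df["label"] == "RFD").to_numpy(dtype=int)
        params, scores = tune_multisource_cv(X, y, df["source"].to_numpy(), fam)
        chosen = fam.grid.index(params)
        assert scores[chosen] == max(scores)

    def test_tie_breaks_to_simpler(self):
        def build(params, seed):
            return LogisticRegression(C=1.0, max_iter=500)  # identical models

        fam = ModelFamily("same", build, [{"v": "simple"}, {"v": "complex"}])
        df = _toy_dataset()
        X = df[["f1", "f2"]].to_numpy()
        y = (df["label"] == "RFD").to_numpy(dtype=int)
        params, _ = tune_multisource_cv(X, y, df["source"].to_numpy(), fam)
        assert params == {"v": "simple"}

    def test_degenerate_fold_raises(self):
        df = _toy_dataset(30, 30)
        df.loc[df["source"] == "gicu-like", "label"] = "RFD"
        X = df[["f1", "f2"]].to_numpy()
        y = (df["label"] == "RFD").to_numpy(dtype=int)
        with pytest.raises(ValueError, match="degenerate"):
            tune_multisource_cv(X, y, df["source"].to_numpy(), logistic_family())

    def test_empty_grid_raises(self):
        fam = ModelFamily("none", lambda p, s: None, [])
        with pytest.raises(ValueError):
            tune_multisource_cv(np.zeros((4, 1)), np.array([0, 1, 0, 1]), np.array(["a", "a", "b", "b"]), fam)


class TestFitFinal:
    def test_separable_data_trains_to_auroc_one(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_final(X, y, logistic_family(), {"C": 10.0})
        assert auroc(model.predict_proba(X)[:, 1], y) == 1.0

    def test_null_labels_auroc_near_half(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(2000, 3))
        y = rng.integers(0, 2, size=2000)
        model = fit_final(X[:1000], y[:1000], logistic_family(), {"C": 1.0})
        score = auroc(model.predict_proba(X[1000:])[:, 1], y[1000:])
        assert abs(score - 0.5) < 0.05  # permutation-null scale

    def test_deterministic_scoring(self):
        X = np.array([[0.0], [1.0], [0.2], [0.8]])
        y = np.array([0, 1, 0, 1])
        model = fit_final(X, y, forest_family(n_estimators=20), {"max_depth": 3, "min_samples_leaf": 1}, seed=3)
        p1 = model.predict_proba(np.array([[0.5]]))[0, 1]
        p2 = model.predict_proba(np.array([[0.5]]))[0, 1]
        assert p1 == p2

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_final(np.zeros((3, 1)), np.array([1, 1, 1]), logistic_family(), {"C": 1.0})


class TestPermutationImportance:
    def _fitted(self, seed=0, n=1500):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        logit = 3.0 * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        model = LogisticRegression(max_iter=500).fit(X, y)
        return model, X, y

    def test_null_feature_importance_near_zero(self):
        model, X, y = self._fitted()
        imp = permutation_importance(model, X, y, n_repeats=10, rng=np.random.default_rng(1))
        assert abs(imp[2]) < 0.02  # independent of y: importance ~ 0

    def test_planted_feature_attains_max(self):
        model, X, y = self._fitted()
        imp = permutation_importance(model, X, y, n_repeats=5, rng=np.random.default_rng(2))
        assert int(np.argmax(imp)) == 0

    def test_identity_permutation_gives_exact_zero(self):
        model, X, y = self._fitted(n=200)

        class IdentityRng:
            def permutation(self, n):
                return np.arange(n)

        imp = permutation_importance(model, X, y, n_repeats=2, rng=IdentityRng())
        assert np.all(imp == 0.0)

    def test_bad_repeats(self):
        model, X, y = self._fitted(n=100)
        with pytest.raises(ValueError):
            permutation_importance(model, X, y, n_repeats=0)


@pytest.fixture(scope="module")
def experiment(small_df):
    return run_experiment(
        small_df,
        n_splits=2,
        seed=42,
        spec=SPEC,
        families=[logistic_family(cs=[0.1, 1.0]), forest_family(n_estimators=25, grid=[{"max_depth": 4, "min_samples_leaf": 2}])],
        feature_set="base",
        n_permutation_repeats=2,
    )


class TestRunExperiment:
    def test_reproducible_under_same_seed(self, small_df, experiment):
        again = run_experiment(
            small_df,
            n_splits=2,
            seed=42,
            spec=SPEC,
            families=[logistic_family(cs=[0.1, 1.0]), forest_family(n_estimators=25, grid=[{"max_depth": 4, "min_samples_leaf": 2}])],
            feature_set="base",
            n_permutation_repeats=2,
        )
        pd.testing.assert_frame_equal(experiment.metrics, again.metrics)
        pd.testing.assert_frame_equal(experiment.importances, again.importances)

    def test_systems_and_cohorts_present(self, experiment):
        assert set(experiment.metrics["system"]) == {"LC", "RF", "NLD", "NLD_weighted"}
        assert set(experiment.metrics["cohort"]) == {"gicu-like", "mimic-like"}

    def test_aggregates_over_configured_splits(self, experiment):
        counts = experiment.metrics.groupby(["cohort", "system", "metric"])["value"].count()
        assert (counts == 2).all()

    def test_ranking_agreement_in_range(self, experiment):
        rho = experiment.ranking_agreement("LC", "RF")
        assert -1.0 <= rho <= 1.0

    def test_single_split_sd_zero_and_warns(self, small_df, caplog):
        with caplog.at_level("WARNING"):
            res = run_experiment(
                small_df,
                n_splits=1,
                seed=0,
                spec=SPEC,
                families=[logistic_family(cs=[1.0])],
                feature_set="base",
                n_permutation_repeats=1,
            )
        assert "n_splits=1" in caplog.text
        assert (res.metric_summary()["std"] == 0.0).all()

    def test_extended_feature_set_suffix(self, small_df):
        res = run_experiment(
            small_df,
            n_splits=1,
            seed=0,
            spec=SPEC,
            families=[logistic_family(cs=[1.0])],
            feature_set="extended",
            n_permutation_repeats=1,
        )
        assert set(res.metrics["system"]) == {"LC_extended"}
        assert len(res.feature_names) == 22
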