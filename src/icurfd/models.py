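"""Classifier training under the multiple-source split/tune/retrain protocol.

One experiment iteration: hold out 30% of the smaller source cohort plus an
equal-sized test set from the larger cohort; tune hyperparameters by
two-fold multiple-source cross-validation (fit on one cohort, validate
AUROC on the other, both directions); retrain the selected model on the
pooled training data; evaluate per-cohort metrics and permutation feature
importance.  Repeating over many random splits yields mean/SD estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from . import metrics
from .criteria import (
    CriteriaThresholds,
    evaluate_tests,
    nld_score,
    weighted_score,
    weights_from_importance,
)
from .features import BASE_FEATURES, EXTENDED_FEATURES, standardise

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    """Held-out test-set rule for the two source cohorts.

    ``fraction_source`` donates ``test_fraction`` of its instances
    (rounded to nearest) to the test set; ``matched_source`` donates an
    equal-sized test set sampled without replacement.
    """

    fraction_source: str = "gicu-like"
    matched_source: str = "mimic-like"
    test_fraction: float = 0.30


@dataclass
class ModelFamily:
    """A tunable classifier family.

    ``grid`` is ordered from simplest to most complex; grid ties during
    tuning resolve toward the earlier (simpler) entry.
    """

    name: str
    builder: Callable[[Mapping, int], object]
    grid: list[dict]


def logistic_family(cs: Sequence[float] = (0.01, 0.1, 1.0, 10.0)) -> ModelFamily:
    def build(params: Mapping, seed: int) -> LogisticRegression:
        return LogisticRegression(C=params["C"], max_iter=2000, solver="lbfgs")

    return ModelFamily("LC", build, [{"C": float(c)} for c in cs])


def forest_family(
    n_estimators: int = 100,
    grid: Sequence[Mapping] | None = None,
) -> ModelFamily:
    grid = list(grid) if grid is not None else [
        {"max_depth": 4, "min_samples_leaf": 5},
        {"max_depth": 8, "min_samples_leaf": 2},
        {"max_depth": None, "min_samples_leaf": 1},
    ]

    def build(params: Mapping, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=params["max_depth"],
            min_samples_leaf=params["min_samples_leaf"],
            random_state=seed,
            n_jobs=1,
        )

    return ModelFamily("RF", build, [dict(g) for g in grid])


def multisource_split(
    dataset: pd.DataFrame,
    spec: SplitSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Split per the 30% / equal-size rule; returns (train, {source: test})."""
    sources = set(dataset["source"])
    if {spec.fraction_source, spec.matched_source} - sources:
        raise ValueError(
            f"dataset must contain both sources {spec.fraction_source!r} and "
            f"{spec.matched_source!r}; has {sorted(sources)}"
        )
    frac_idx = dataset.index[dataset["source"] == spec.fraction_source].to_numpy()
    match_idx = dataset.index[dataset["source"] == spec.matched_source].to_numpy()
    n_test = int(round(spec.test_fraction * len(frac_idx)))
    if n_test < 1:
        raise ValueError("fraction-source test set would be empty")
    if n_test > len(match_idx):
        raise ValueError(
            f"matched source has {len(match_idx)} instances; cannot hold out {n_test}"
        )
    test_a = rng.choice(frac_idx, size=n_test, replace=False)
    test_b = rng.choice(match_idx, size=n_test, replace=False)
    test_ids = set(test_a) | set(test_b)
    train = dataset.loc[[i for i in dataset.index if i not in test_ids]]
    return train, {
        spec.fraction_source: dataset.loc[sorted(test_a)],
        spec.matched_source: dataset.loc[sorted(test_b)],
    }


def tune_multisource_cv(
    X: np.ndarray,
    y: np.ndarray,
    source: np.ndarray,
    family: ModelFamily,
    seed: int = 0,
) -> tuple[dict, list[float]]:
    """Two-fold multiple-source CV: each fold is one entire source cohort.

    Returns the grid point maximising mean fold AUROC (ties toward the
    earlier, simpler grid entry) and all grid scores.
    """
    if not family.grid:
        raise ValueError("empty hyperparameter grid")
    names = np.unique(source)
    if len(names) != 2:
        raise ValueError(f"training data must contain exactly two sources, got {list(names)}")
    folds = [(source == names[0]), (source == names[1])]
    for mask in folds:
        if len(np.unique(y[mask])) < 2:
            raise ValueError("degenerate fold: only one class present")
    scores: list[float] = []
    for params in family.grid:
        fold_scores = []
        for fit_mask, val_mask in ((folds[0], folds[1]), (folds[1], folds[0])):
            model = family.builder(params, seed)
            model.fit(X[fit_mask], y[fit_mask])
            s = model.predict_proba(X[val_mask])[:, 1]
            fold_scores.append(metrics.auroc(s, y[val_mask]))
        scores.append(float(np.mean(fold_scores)))
    best = int(np.argmax(scores))  # argmax takes the first max: simplest wins ties
    return dict(family.grid[best]), scores


def fit_final(X: np.ndarray, y: np.ndarray, family: ModelFamily, params: Mapping, seed: int = 0):
    """Retrain the tuned model on the full pooled training data."""
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit on single-class training data")
    model = family.builder(params, seed)
    model.fit(X, y)
    return model


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean AUROC drop when each feature column is permuted.

    ``importance_f = mean over repeats of (baseline AUROC - permuted AUROC)``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = rng or np.random.default_rng()
    baseline = metrics.auroc(model.predict_proba(X)[:, 1], y)
    n, d = X.shape
    out = np.zeros(d)
    for j in range(d):
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            drops.append(baseline - metrics.auroc(model.predict_proba(Xp)[:, 1], y))
        out[j] = float(np.mean(drops))
    return out


@dataclass
class ExperimentResult:
    """Per-split metrics/importances and their aggregates."""

    metrics: pd.DataFrame  # split, cohort, system, metric, value
    importances: pd.DataFrame  # split, system, feature, importance
    coefficients: pd.DataFrame  # split, feature, coefficient (logistic)
    n_splits: int
    feature_names: list[str] = field(default_factory=list)

    def metric_summary(self) -> pd.DataFrame:
        """Mean and SD of every metric per cohort and system."""
        g = self.metrics.groupby(["cohort", "system", "metric"])["value"]
        out = g.agg(["mean", "std"]).reset_index()
        out["std"] = out["std"].fillna(0.0)  # single split: SD 0 by convention
        return out

    def importance_summary(self) -> pd.DataFrame:
        """Mean/SD importance and rank (0 = most important) per system."""
        g = self.importances.groupby(["system", "feature"])["importance"]
        out = g.agg(["mean", "std"]).reset_index()
        out["std"] = out["std"].fillna(0.0)
        out["rank"] = (
            out.groupby("system")["mean"].rank(ascending=False, method="first").astype(int) - 1
        )
        return out.sort_values(["system", "rank"]).reset_index(drop=True)

    def ranking_agreement(self, system_a: str = "LC", system_b: str = "RF") -> float:
        """Spearman correlation between two systems' importance rankings."""
        s = self.importance_summary()
        a = s[s["system"] == system_a].set_index("feature")["rank"]
        b = s[s["system"] == system_b].set_index("feature")["rank"]
        common = sorted(set(a.index) & set(b.index))
        return metrics.spearman_rank(a.loc[common].to_numpy(), b.loc[common].to_numpy())


def nld_scores(features_df: pd.DataFrame, thresholds: CriteriaThresholds, weights=None) -> np.ndarray:
    """Criteria-based probability scores for a raw (unstandardised) matrix."""
    out = np.empty(len(features_df))
    records = features_df[BASE_FEATURES].to_dict("records")
    for i, row in enumerate(records):
        result = evaluate_tests(row, thresholds)
        out[i] = weighted_score(result, weights) if weights is not None else nld_score(result)
    return out


def run_experiment(
    dataset: pd.DataFrame,
    n_splits: int = 100,
    seed: int = 0,
    spec: SplitSpec | None = None,
    families: Sequence[ModelFamily] | None = None,
    feature_set: str = "base",
    thresholds: CriteriaThresholds | None = None,
    n_permutation_repeats: int = 5,
    include_nld: bool = True,
) -> ExperimentResult:
    """Repeat split -> tune -> retrain -> evaluate over ``n_splits`` splits.

    ``dataset`` is an imputed feature matrix with ``source`` and ``label``
    (1 = RFD) columns.  The criteria-based scorers (uniform and
    importance-weighted) are evaluated on the raw features of the same test
    sets; the weighted variant uses the logistic importances of its own
    split.  One master seed drives per-split child seeds for splitting,
    tuning, fitting and permutation.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if feature_set not in ("base", "extended"):
        raise ValueError("feature_set must be 'base' or 'extended'")
    spec = spec or SplitSpec()
    thresholds = thresholds or CriteriaThresholds()
    families = list(families) if families is not None else [logistic_family(), forest_family()]
    feat_names = BASE_FEATURES if feature_set == "base" else EXTENDED_FEATURES
    suffix = "" if feature_set == "base" else "_extended"

    if n_splits == 1:
        logger.warning("n_splits=1: SDs will be reported as 0 by convention")

    metric_rows, importance_rows, coef_rows = [], [], []
    children = np.random.SeedSequence(seed).spawn(n_splits)
    for split_i, child in enumerate(children):
        try:
            rng = np.random.default_rng(child)
            fit_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            train, tests = multisource_split(dataset, spec, rng)
            Xtr_raw = train[list(feat_names)]
            ytr = (train["label"] == "RFD").to_numpy(dtype=int)
            Xte_raw = {c: t[list(feat_names)] for c, t in tests.items()}
            yte = {c: (t["label"] == "RFD").to_numpy(dtype=int) for c, t in tests.items()}
            order = list(tests)
            std = standardise(Xtr_raw, *(Xte_raw[c] for c in order))
            Xtr, rest = std[0], std[1:-1]
            Xte = dict(zip(order, rest))
            pooled_X = np.vstack([Xte[c] for c in order])
            pooled_y = np.concatenate([yte[c] for c in order])

            lc_importance_by_feature: dict[str, float] | None = None
            for family in families:
                params, _ = tune_multisource_cv(
                    Xtr, ytr, train["source"].to_numpy(), family, seed=fit_seed
                )
                model = fit_final(Xtr, ytr, family, params, seed=fit_seed)
                for cohort in order:
                    s = model.predict_proba(Xte[cohort])[:, 1]
                    report = metrics.compute_report(s, yte[cohort])
                    for m, v in report.as_dict().items():
                        metric_rows.append((split_i, cohort, family.name + suffix, m, v))
                imp = permutation_importance(
                    model, pooled_X, pooled_y, n_repeats=n_permutation_repeats, rng=rng
                )
                for f, v in zip(feat_names, imp):
                    importance_rows.append((split_i, family.name + suffix, f, float(v)))
                if family.name == "LC":
                    lc_importance_by_feature = dict(zip(feat_names, imp))
                    for f, c in zip(feat_names, np.ravel(model.coef_)):
                        coef_rows.append((split_i, f, float(c)))

            if include_nld and feature_set == "base":
                for cohort in order:
                    raw = tests[cohort]
                    s = nld_scores(raw, thresholds)
                    report = metrics.compute_report(s, yte[cohort])
                    for m, v in report.as_dict().items():
                        metric_rows.append((split_i, cohort, "NLD", m, v))
                if lc_importance_by_feature is not None:
                    weights = weights_from_importance(
                        {f: lc_importance_by_feature.get(f, 0.0) for f in BASE_FEATURES},
                        thresholds,
                    )
                    for cohort in order:
                        s = nld_scores(tests[cohort], thresholds, weights=weights)
                        report = metrics.compute_report(s, yte[cohort])
                        for m, v in report.as_dict().items():
                            metric_rows.append((split_i, cohort, "NLD_weighted", m, v))
        except Exception:
            logger.error("experiment failed at split %d", split_i)
            raise

    return ExperimentResult(
        metrics=pd.DataFrame(metric_rows, columns=["split", "cohort", "system", "metric", "value"]),
        importances=pd.DataFrame(
            importance_rows, columns=["split", "system", "feature", "importance"]
        ),
        coefficients=pd.DataFrame(coef_rows, columns=["split", "feature", "coefficient"]),
        n_splits=n_splits,
        feature_names=list(feat_names),
    )
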