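"""End-to-end orchestration: generate -> label -> extract -> impute ->
train/evaluate -> report bundle.

The bundle contains tidy per-split metrics, a summary table of mean (SD)
metrics per system and cohort, an importance table with ranks for both
classifier families, ROC/PRC curve files for the first split, and a JSON
run summary with per-stage counts.  Identical config and seed produce a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import metrics as metrics_mod
from .criteria import CriteriaThresholds
from .features import BASE_FEATURES, EXTRA_FEATURES, build_feature_matrix, complete_cases, knn_impute
from .models import (
    SplitSpec,
    forest_family,
    logistic_family,
    multisource_split,
    nld_scores,
    run_experiment,
)
from .synth import CohortConfig, generate_cohort, gicu_like, mimic_like

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort_a: CohortConfig = field(default_factory=lambda: mimic_like(n_patients=1000))
    cohort_b: CohortConfig = field(default_factory=lambda: gicu_like(n_patients=400))
    split: SplitSpec = field(default_factory=SplitSpec)
    n_splits: int = 10
    feature_sets: tuple[str, ...] = ("base", "extended")
    imputation: str = "knn"  # knn | complete-case
    knn_k: int = 5
    n_permutation_repeats: int = 5
    logistic_cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    rf_n_estimators: int = 100
    seed: int = 0

    def validate(self) -> None:
        self.cohort_a.validate()
        self.cohort_b.validate()
        if self.imputation not in ("knn", "complete-case"):
            raise ValueError("imputation must be 'knn' or 'complete-case'")
        for fs in self.feature_sets:
            if fs not in ("base", "extended"):
                raise ValueError(f"unknown feature set {fs!r}")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort_a" in data:
            kwargs["cohort_a"] = _cohort_from_dict(data.pop("cohort_a"))
        if "cohort_b" in data:
            kwargs["cohort_b"] = _cohort_from_dict(data.pop("cohort_b"))
        if "split" in data:
            kwargs["split"] = SplitSpec(**data.pop("split"))
        if "feature_sets" in data:
            kwargs["feature_sets"] = tuple(data.pop("feature_sets"))
        if "logistic_cs" in data:
            kwargs["logistic_cs"] = tuple(data.pop("logistic_cs"))
        kwargs.update(data)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _cohort_from_dict(data: dict) -> CohortConfig:
    base = data.pop("preset", None)
    for key in ("age_median_iqr", "bmi_median_iqr", "los_median_iqr", "discharge_delay_median_iqr"):
        if key in data:
            med, iqr = data[key]
            data[key] = (float(med), (float(iqr[0]), float(iqr[1])))
    if base == "mimic-like":
        return mimic_like(**data)
    if base == "gicu-like":
        return gicu_like(**data)
    return CohortConfig(**data)


def prepare_dataset(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Generate both cohorts, label, extract, and impute.

    Returns the analysis-ready feature DataFrame (metadata + all 22 feature
    columns) and a dict of per-stage counts.
    """
    config.validate()
    counts: dict[str, int | float] = {}
    stays_a = generate_cohort(config.cohort_a)
    stays_b = generate_cohort(config.cohort_b)
    counts["stays_generated"] = len(stays_a) + len(stays_b)

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    instances = cohort_mod.build_dataset([stays_a, stays_b], rng=rng)
    counts["instances"] = len(instances)
    counts["instances_augmented"] = sum(1 for i in instances if i.provenance == "augmented")
    counts["instances_rfd"] = sum(1 for i in instances if i.label == cohort_mod.RFD)

    df = build_feature_matrix(stays_a + stays_b, instances, extended=True)
    feature_cols = BASE_FEATURES + EXTRA_FEATURES
    n_missing = int(df[feature_cols].isna().to_numpy().sum())
    counts["missing_cells"] = n_missing
    if config.imputation == "knn":
        df[feature_cols] = knn_impute(df[feature_cols], k=config.knn_k)
        counts["imputed_cells"] = n_missing
    else:
        before = len(df)
        df = complete_cases(df, feature_cols)
        counts["rows_dropped_incomplete"] = before - len(df)
    return df, counts


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df, counts = prepare_dataset(config)
    df.to_csv(outdir / "features.csv", index=False)

    thresholds = CriteriaThresholds()
    spec = SplitSpec(
        fraction_source=config.cohort_b.name,
        matched_source=config.cohort_a.name,
        test_fraction=config.split.test_fraction,
    )
    all_metrics, all_importances = [], []
    base_result = None
    for fs in config.feature_sets:
        families = [
            logistic_family(config.logistic_cs),
            forest_family(n_estimators=config.rf_n_estimators),
        ]
        result = run_experiment(
            df,
            n_splits=config.n_splits,
            seed=config.seed,
            spec=spec,
            families=families,
            feature_set=fs,
            thresholds=thresholds,
            n_permutation_repeats=config.n_permutation_repeats,
            include_nld=(fs == "base"),
        )
        all_metrics.append(result.metrics)
        all_importances.append(result.importances)
        if fs == "base":
            base_result = result
        last_result = result

    metrics_df = pd.concat(all_metrics, ignore_index=True)
    importances_df = pd.concat(all_importances, ignore_index=True)
    metrics_df.to_csv(outdir / "metrics_tidy.csv", index=False)

    summary = (
        metrics_df.groupby(["cohort", "system", "metric"])["value"].agg(["mean", "std"]).reset_index()
    )
    summary["std"] = summary["std"].fillna(0.0)
    summary["mean_sd"] = summary.apply(lambda r: f"{r['mean']:.4f} ({r['std']:.4f})", axis=1)
    table = summary.pivot(index=["cohort", "metric"], columns="system", values="mean_sd")
    table.to_csv(outdir / "metrics_summary.csv")

    imp = importances_df.groupby(["system", "feature"])["importance"].agg(["mean", "std"]).reset_index()
    imp["std"] = imp["std"].fillna(0.0)
    imp["rank"] = imp.groupby("system")["mean"].rank(ascending=False, method="first").astype(int) - 1
    imp.sort_values(["system", "rank"]).to_csv(outdir / "importance_summary.csv", index=False)

    if base_result is not None:
        agreement = base_result.ranking_agreement("LC", "RF")
    else:
        agreement = last_result.ranking_agreement("LC_extended", "RF_extended")

    _write_curves(df, config, spec, thresholds, outdir)

    counts["ranking_agreement_spearman"] = agreement
    counts["n_splits"] = config.n_splits
    (outdir / "run_summary.json").write_text(json.dumps(counts, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", counts)
    return counts


def _write_curves(df, config, spec, thresholds, outdir: Path) -> None:
    """ROC/PRC curve CSVs for the criteria scorer on split 0's test sets."""
    child = np.random.SeedSequence(config.seed).spawn(1)[0]
    rng = np.random.default_rng(child)
    _, tests = multisource_split(df, spec, rng)
    rows_roc, rows_prc = [], []
    for cohort_name, test in tests.items():
        y = (test["label"] == "RFD").to_numpy(dtype=int)
        s = nld_scores(test, thresholds)
        roc = metrics_mod.roc_curve(s, y)
        for f, t in zip(roc.fpr, roc.tpr):
            rows_roc.append((cohort_name, "NLD", float(f), float(t)))
        prc = metrics_mod.prc_curve(s, y)
        for r, p in zip(prc.recall, prc.precision):
            rows_prc.append((cohort_name, "NLD", float(r), float(p)))
    pd.DataFrame(rows_roc, columns=["cohort", "system", "fpr", "tpr"]).to_csv(
        outdir / "roc_curves.csv", index=False
    )
    pd.DataFrame(rows_prc, columns=["cohort", "system", "recall", "precision"]).to_csv(
        outdir / "prc_curves.csv", index=False
    )


def runconfig_to_yaml(config: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
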