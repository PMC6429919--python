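# icurfd

Readiness-for-discharge (RFD) classification for ICU electronic health
record data, built as a reusable, fully tested pipeline on top of a
synthetic two-cohort EHR generator — so every stage can be exercised and
validated without access to protected patient data.

The pipeline covers:

- **Codified discharge criteria** (`icurfd.criteria`) — 15 inclusive
  threshold tests on routinely collected vitals and labs, the sustained
  all-criteria discharge rule, the normalised count/15 score, and an
  importance-weighted score.
- **Cohort labelling** (`icurfd.cohort`) — RFD/NRFD labels anchored at the
  callout time by eventual outcome (in-hospital death and/or ICU
  readmission), plus negative-class augmentation sampled 3–8 days before
  callout (and ≥ 24 h after admission) to balance class sizes.
- **Feature extraction** (`icurfd.features`) — 18 base physiological
  features (plus age, sex, BMI, hours-since-admission in the extended set)
  from a 4 h window with a 36 h fallback for sparse labs; k-NN imputation
  and train-fitted standardisation.
- **Model suite** (`icurfd.models`) — logistic and random-forest
  classifiers trained under a multiple-source protocol: per-split 30% /
  equal-size held-out test sets, two-fold cross-source hyperparameter
  tuning, retraining on the pooled training data, repeated over many random
  splits; permutation feature importance (mean AUROC drop).
- **Metrics** (`icurfd.metrics`) — ROC/PRC curves, AUROC, partial AUROC
  (FPR ≤ 0.3), Brier score, and accuracy/F1/sensitivity at a
  specificity-0.7 operating point located by linear interpolation in ROC
  space; Spearman rank agreement between importance rankings.
- **Synthetic generator** (`icurfd.synth`) — two source cohorts
  ("mimic-like", "gicu-like") with realistic event structure, frequent
  vitals / sparse labs, missingness, a per-patient recovery ramp toward
  normal physiology, and a *planted* logistic outcome model on
  callout-time features, which downstream stages are tested against
  (parameter recovery, importance ranking, score ordering).

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (boundary-exact
rule checks, an exhaustive pair-counting ROC oracle, augmentation-window
invariants, planted-coefficient recovery, score ordering, and byte-level
pipeline determinism); the stochastic ones share a module-scoped
20-split experiment and take a couple of minutes.

## Command line

```bash
# one-command pipeline: generate -> label -> extract -> train -> report
icurfd run-all --out results/run1 --seed 0
icurfd run-all --config run.yaml --out results/run2

# or stage by stage
icurfd generate --preset gicu-like --n-patients 500 --seed 1 --out cohorts/gicu
icurfd generate --preset mimic-like --n-patients 2000 --seed 2 --out cohorts/mimic
icurfd build --cohort cohorts/gicu --cohort cohorts/mimic --out instances.csv
icurfd extract --cohort cohorts/gicu --cohort cohorts/mimic \
    --instances instances.csv --out features.csv
icurfd train --features features.csv --n-splits 10 --out results/train
icurfd evaluate --scores scores.csv
```

A `run-all` bundle contains tidy per-split metrics, a mean (SD) summary
table per system (NLD, NLD_weighted, LC, RF, LC_extended, RF_extended) and
cohort, an importance table with ranks, ROC/PRC curve CSVs and a JSON run
summary. Identical config and seed give a byte-identical bundle.

Example `run.yaml`:

```yaml
cohort_a: {preset: mimic-like, n_patients: 2000, seed: 0}
cohort_b: {preset: gicu-like, n_patients: 800, seed: 1}
n_splits: 25
feature_sets: [base, extended]
imputation: knn
seed: 7
```

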