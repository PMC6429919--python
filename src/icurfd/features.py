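"""Windowed feature extraction, k-NN imputation and standardisation.

Eighteen base physiological features are derived from the fifteen tracked
variables: paired min/max features for respiratory rate, heart rate and
temperature, and a single feature for everything else.  An extended set adds
age, sex, BMI and hours since admission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .records import PatientStay

#: The 18 base physiological features, in canonical (report) order.
BASE_FEATURES = [
    "airway",
    "fio2",
    "spo2_min",
    "hco3",
    "resp_min",
    "resp_max",
    "bp_min",
    "hr_min",
    "hr_max",
    "pain",
    "gcs_min",
    "temp_min",
    "temp_max",
    "haemoglobin",
    "k",
    "na",
    "creatinine",
    "bun",
]

#: Demographic / temporal features of the extended set.
EXTRA_FEATURES = ["age", "sex", "bmi", "hours_since_admission"]

EXTENDED_FEATURES = BASE_FEATURES + EXTRA_FEATURES

# feature -> (source variable, window aggregation).  Single-feature vitals
# take the clinically conservative extreme (the direction in which the
# discharge test fails); labs take the most recent observation.
_AGGREGATIONS: dict[str, tuple[str, str]] = {
    "airway": ("airway", "min"),
    "fio2": ("fio2", "max"),
    "spo2_min": ("spo2", "min"),
    "hco3": ("hco3", "last"),
    "resp_min": ("resp", "min"),
    "resp_max": ("resp", "max"),
    "bp_min": ("bp", "min"),
    "hr_min": ("hr", "min"),
    "hr_max": ("hr", "max"),
    "pain": ("pain", "max"),
    "gcs_min": ("gcs", "min"),
    "temp_min": ("temp", "min"),
    "temp_max": ("temp", "max"),
    "haemoglobin": ("haemoglobin", "last"),
    "k": ("k", "last"),
    "na": ("na", "last"),
    "creatinine": ("creatinine", "last"),
    "bun": ("bun", "last"),
}


@dataclass
class FeatureVector:
    """Feature values for one instance at one reference time.

    Missing features are NaN.  Iteration and ``[]`` access behave like a
    read-only mapping over the feature names present.
    """

    values: dict[str, float]
    stay_id: str | None = None
    t_ref: int | None = None

    def __getitem__(self, feature: str) -> float:
        return self.values[feature]

    def __contains__(self, feature: str) -> bool:
        return feature in self.values

    def __iter__(self):
        return iter(self.values)

    def is_missing(self, feature: str) -> bool:
        v = self.values.get(feature, math.nan)
        return not (v == v)  # NaN check

    def as_array(self, features: Sequence[str]) -> np.ndarray:
        return np.array([self.values.get(f, math.nan) for f in features], dtype=float)


def extract_features(
    stay: PatientStay,
    t_ref: float,
    window_hours: float = 4.0,
    fallback_hours: float = 36.0,
    extended: bool = False,
) -> FeatureVector:
    """Extract the base (or extended) features at reference time ``t_ref``.

    Per variable, observations in the half-open window
    ``(t_ref - window_hours, t_ref]`` are aggregated; if the window is empty
    the longer fallback window is used instead; if that is also empty every
    feature of the variable is marked missing (NaN).

    Raises ``ValueError`` if ``t_ref`` precedes admission.
    """
    if t_ref < stay.admission_time:
        raise ValueError(
            f"t_ref {t_ref} precedes admission ({stay.admission_time}) "
            f"for stay {stay.stay_id}"
        )
    windows: dict[str, np.ndarray] = {}
    for var, (times, vals) in stay.series.items():
        hi = np.searchsorted(times, t_ref, side="right")
        lo = np.searchsorted(times, t_ref - window_hours * 60.0, side="right")
        if hi == lo:  # fallback only when the short window is empty
            lo = np.searchsorted(times, t_ref - fallback_hours * 60.0, side="right")
        if hi > lo:
            windows[var] = vals[lo:hi]

    out: dict[str, float] = {}
    for feat, (var, how) in _AGGREGATIONS.items():
        win = windows.get(var)
        if win is None or len(win) == 0:
            out[feat] = math.nan
        elif how == "min":
            out[feat] = float(win.min())
        elif how == "max":
            out[feat] = float(win.max())
        else:  # most recent
            out[feat] = float(win[-1])

    if extended:
        out["age"] = float(stay.age)
        out["sex"] = float(stay.sex)
        out["bmi"] = float(stay.bmi)
        out["hours_since_admission"] = (t_ref - stay.admission_time) / 60.0

    return FeatureVector(out, stay_id=stay.stay_id, t_ref=int(t_ref))


def build_feature_matrix(
    stays: Iterable[PatientStay],
    instances,
    window_hours: float = 4.0,
    fallback_hours: float = 36.0,
    extended: bool = True,
) -> pd.DataFrame:
    """Feature matrix for a collection of labelled instances.

    Returns a DataFrame with the metadata columns ``stay_id, source,
    t_ref_minutes, label, provenance`` followed by feature columns.
    """
    by_id = {s.stay_id: s for s in stays}
    names = EXTENDED_FEATURES if extended else BASE_FEATURES
    rows = []
    for inst in instances:
        stay = by_id[inst.stay_id]
        fv = extract_features(
            stay,
            inst.t_ref,
            window_hours=window_hours,
            fallback_hours=fallback_hours,
            extended=extended,
        )
        row = {
            "stay_id": inst.stay_id,
            "source": inst.source,
            "t_ref_minutes": inst.t_ref,
            "label": inst.label,
            "provenance": inst.provenance,
        }
        row.update({f: fv.values[f] for f in names})
        rows.append(row)
    return pd.DataFrame(rows)


def knn_impute(matrix: pd.DataFrame | np.ndarray, k: int = 5) -> pd.DataFrame | np.ndarray:
    """Fill missing cells with the k-nearest-neighbour mean.

    Distances are Euclidean over mutually observed features after
    per-column standardisation; observed cells are returned unchanged.
    A column with no observed value at all raises ``ValueError`` naming
    the feature.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    obs = ~np.isnan(X)
    if not obs.any(axis=0).all():
        j = int(np.flatnonzero(~obs.any(axis=0))[0])
        name = matrix.columns[j] if is_frame else f"column {j}"
        raise ValueError(f"feature {name!r} has no observed values; cannot impute")
    if obs.all():
        return matrix.copy() if is_frame else X.copy()

    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd
    filled = KNNImputer(n_neighbors=k, weights="uniform").fit_transform(Z)
    out = filled * sd + mean
    out[obs] = X[obs]  # never perturb observed cells
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def complete_cases(matrix: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    """Drop rows with any missing value in ``features`` (sensitivity mode)."""
    return matrix.dropna(subset=list(features)).reset_index(drop=True)


@dataclass
class StandardiseParams:
    """Column means and sample SDs fitted on a training matrix."""

    mean: np.ndarray
    sd: np.ndarray
    columns: list[str] | None = field(default=None)

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        A = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        with np.errstate(invalid="ignore"):
            Z = (A - self.mean) / np.where(self.sd > 0, self.sd, 1.0)
        return np.where(self.sd > 0, Z, 0.0)


def standardise(train: pd.DataFrame | np.ndarray, *others):
    """Standardise with mean/SD fitted on ``train`` only.

    Returns ``(train_z, *others_z, params)``.  Sample SD (ddof=1) is used;
    zero-variance columns map to 0 in every matrix.
    """
    A = train.to_numpy(dtype=float) if isinstance(train, pd.DataFrame) else np.asarray(train, float)
    if A.size == 0:
        raise ValueError("empty training matrix")
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1) if A.shape[0] > 1 else np.zeros(A.shape[1])
    cols = list(train.columns) if isinstance(train, pd.DataFrame) else None
    params = StandardiseParams(mean=mean, sd=sd, columns=cols)
    out = [params.transform(train)] + [params.transform(m) for m in others]
    return (*out, params)
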