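"""Plain-text persistence for cohorts and configuration objects.

A cohort directory holds two CSVs: ``stays.csv`` with one row of metadata
per stay, and ``observations.csv`` in long format (stay_id, variable,
t_minutes, value).  The round trip is lossless for generated cohorts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import NORMAL_BANDS, PatientStay
from .synth import CohortConfig

STAY_COLUMNS = [
    "stay_id",
    "source",
    "admission_minutes",
    "callout_minutes",
    "discharge_minutes",
    "age",
    "sex",
    "bmi",
    "died_in_hospital",
    "readmitted",
]

OBS_COLUMNS = ["stay_id", "variable", "t_minutes", "value"]


class CohortParseError(ValueError):
    """A cohort file contains a malformed or invariant-violating row."""


def write_cohort(stays: list[PatientStay], path: str | Path) -> None:
    """Write a cohort to ``path`` (a directory, created if needed).

    Variables with no observations are dropped; on read they are simply
    absent from the stay's series.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        {
            "stay_id": [s.stay_id for s in stays],
            "source": [s.source for s in stays],
            "admission_minutes": [s.admission_time for s in stays],
            "callout_minutes": [s.callout_time for s in stays],
            "discharge_minutes": [s.icu_discharge_time for s in stays],
            "age": [s.age for s in stays],
            "sex": [s.sex for s in stays],
            "bmi": [s.bmi for s in stays],
            "died_in_hospital": [int(s.died_in_hospital) for s in stays],
            "readmitted": [int(s.readmitted) for s in stays],
        }
    )
    meta.to_csv(path / "stays.csv", index=False)

    ids, variables, ts, vs = [], [], [], []
    for s in stays:
        for var, (t, v) in s.series.items():
            if len(t) == 0:
                continue
            ids.extend([s.stay_id] * len(t))
            variables.extend([var] * len(t))
            ts.append(np.asarray(t))
            vs.append(np.asarray(v))
    obs = pd.DataFrame(
        {
            "stay_id": ids,
            "variable": variables,
            "t_minutes": np.concatenate(ts) if ts else np.array([], dtype=np.int64),
            "value": np.concatenate(vs) if vs else np.array([], dtype=float),
        }
    )
    obs.to_csv(path / "observations.csv", index=False)


def read_cohort(path: str | Path) -> list[PatientStay]:
    """Read a cohort written by :func:`write_cohort`, validating invariants.

    Malformed rows raise :class:`CohortParseError` naming the file and the
    1-based line number (header is line 1).
    """
    path = Path(path)
    meta = pd.read_csv(path / "stays.csv", float_precision="round_trip")
    missing = set(STAY_COLUMNS) - set(meta.columns)
    if missing:
        raise CohortParseError(f"stays.csv: missing columns {sorted(missing)}")
    obs = pd.read_csv(path / "observations.csv", float_precision="round_trip")
    if set(OBS_COLUMNS) - set(obs.columns):
        raise CohortParseError("observations.csv: missing columns")

    intervals: dict[str, tuple[int, int]] = {}
    stays: dict[str, PatientStay] = {}
    for i, row in enumerate(meta.itertuples(index=False)):
        line = i + 2
        try:
            adm, call, dis = int(row.admission_minutes), int(row.callout_minutes), int(row.discharge_minutes)
        except (TypeError, ValueError) as exc:
            raise CohortParseError(f"stays.csv line {line}: non-integer timestamp") from exc
        if not adm < call <= dis:
            raise CohortParseError(
                f"stays.csv line {line}: require admission < callout <= discharge"
            )
        stay = PatientStay(
            stay_id=str(row.stay_id),
            source=str(row.source),
            admission_time=adm,
            callout_time=call,
            icu_discharge_time=dis,
            age=float(row.age),
            sex=int(row.sex),
            bmi=float(row.bmi),
            died_in_hospital=bool(row.died_in_hospital),
            readmitted=bool(row.readmitted),
            series={},
        )
        stays[stay.stay_id] = stay
        intervals[stay.stay_id] = (adm, dis)

    sid = obs["stay_id"].astype(str).to_numpy()
    var = obs["variable"].to_numpy()
    t = obs["t_minutes"].to_numpy()
    val = pd.to_numeric(obs["value"], errors="coerce").to_numpy()

    bad = np.flatnonzero(np.isnan(val))
    if len(bad):
        raise CohortParseError(
            f"observations.csv line {bad[0] + 2}: non-numeric value {obs['value'].iloc[bad[0]]!r}"
        )
    known = np.isin(var, list(NORMAL_BANDS))
    if not known.all():
        i = int(np.flatnonzero(~known)[0])
        raise CohortParseError(f"observations.csv line {i + 2}: unknown variable {var[i]!r}")
    lo = pd.Series(sid).map({k: v[0] for k, v in intervals.items()}).to_numpy()
    hi = pd.Series(sid).map({k: v[1] for k, v in intervals.items()}).to_numpy()
    if np.isnan(lo).any():
        i = int(np.flatnonzero(np.isnan(lo))[0])
        raise CohortParseError(f"observations.csv line {i + 2}: unknown stay_id {sid[i]!r}")
    outside = (t < lo) | (t > hi)
    if outside.any():
        i = int(np.flatnonzero(outside)[0])
        raise CohortParseError(
            f"observations.csv line {i + 2}: timestamp {t[i]} outside stay "
            f"interval [{int(lo[i])}, {int(hi[i])}]"
        )
    order = np.lexsort((t, var, sid)) if len(obs) else np.array([], dtype=int)
    sid, var, t, val = sid[order], var[order], t[order], val[order]
    # group contiguous (stay, variable) runs
    i = 0
    while i < len(sid):
        j = i
        while j < len(sid) and sid[j] == sid[i] and var[j] == var[i]:
            j += 1
        stays[sid[i]].series[var[i]] = (
            t[i:j].astype(np.int64),
            val[i:j].astype(float),
        )
        i = j

    out = list(stays.values())
    for s in out:
        s.validate()
    return out


def config_to_yaml(config: CohortConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_from_yaml(path: str | Path) -> CohortConfig:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("age_median_iqr", "bmi_median_iqr", "los_median_iqr", "discharge_delay_median_iqr"):
        if key in data and data[key] is not None:
            med, iqr = data[key]
            data[key] = (float(med), (float(iqr[0]), float(iqr[1])))
    cfg = CohortConfig(**data)
    cfg.validate()
    return cfg
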