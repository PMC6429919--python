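"""Labelled-instance construction: callout labels plus augmented negatives.

A stay is ready-for-discharge (RFD) at callout when the patient left
hospital alive without ICU readmission, and not-ready (NRFD) otherwise.
Because negative outcomes are rare, additional NRFD instances are sampled
between 3 and 8 days before callout (and at least 24 h after admission),
when the patient is assumed to still need critical care regardless of
eventual outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import PatientStay

logger = logging.getLogger(__name__)

RFD = "RFD"
NRFD = "NRFD"

MIN_LEAD_MINUTES = 3 * 1440
MAX_LEAD_MINUTES = 8 * 1440
MIN_MINUTES_FROM_ADMISSION = 24 * 60


@dataclass(frozen=True)
class LabeledInstance:
    stay_id: str
    source: str
    t_ref: int
    label: str  # RFD | NRFD
    provenance: str  # callout | augmented


def label_at_callout(stay: PatientStay) -> LabeledInstance | None:
    """Label a stay at its callout time by eventual outcome.

    Returns ``None`` (with a warning) when the stay has no callout.
    """
    if stay.callout_time is None:
        logger.warning("stay %s has no callout time; skipped", stay.stay_id)
        return None
    label = NRFD if (stay.died_in_hospital or stay.readmitted) else RFD
    return LabeledInstance(
        stay_id=stay.stay_id,
        source=stay.source,
        t_ref=int(stay.callout_time),
        label=NRFD if label == NRFD else RFD,
        provenance="callout",
    )


def _valid_interval(stay: PatientStay) -> tuple[int, int] | None:
    """[callout - 8 d, callout - 3 d] intersected with [admission + 24 h, inf)."""
    lo = max(stay.callout_time - MAX_LEAD_MINUTES, stay.admission_time + MIN_MINUTES_FROM_ADMISSION)
    hi = stay.callout_time - MIN_LEAD_MINUTES
    if hi < lo:
        return None
    return int(lo), int(hi)


def augment_negatives(
    stays: Sequence[PatientStay],
    target_n: int,
    rng: np.random.Generator,
    max_per_stay: int = 1,
) -> list[LabeledInstance]:
    """Sample up to ``target_n`` NRFD instances 3-8 days before callout.

    Reference times are uniform over each stay's valid interval.  Stays are
    drawn in shuffled order, at most once per round, for ``max_per_stay``
    rounds; fewer than ``target_n`` instances are returned when the pool is
    exhausted (logged).  No stay contributes two instances at the same time.
    """
    if target_n < 0:
        raise ValueError("target_n must be >= 0")
    eligible = [(s, iv) for s in stays if (iv := _valid_interval(s)) is not None]
    out: list[LabeledInstance] = []
    used: dict[str, set[int]] = {}
    for _ in range(max_per_stay):
        if len(out) >= target_n or not eligible:
            break
        order = rng.permutation(len(eligible))
        for idx in order:
            if len(out) >= target_n:
                break
            stay, (lo, hi) = eligible[idx]
            taken = used.setdefault(stay.stay_id, set())
            if len(taken) > hi - lo:  # interval exhausted
                continue
            for _attempt in range(20):
                t_ref = int(rng.integers(lo, hi + 1))
                if t_ref not in taken:
                    break
            else:
                continue
            taken.add(t_ref)
            out.append(
                LabeledInstance(
                    stay_id=stay.stay_id,
                    source=stay.source,
                    t_ref=t_ref,
                    label=NRFD,
                    provenance="augmented",
                )
            )
    if len(out) < target_n:
        logger.info(
            "augmentation pool exhausted: %d of %d requested instances", len(out), target_n
        )
    return out


def build_dataset(
    cohorts: Sequence[Sequence[PatientStay]],
    rng: np.random.Generator | int | None = None,
    max_per_stay: int = 2,
) -> list[LabeledInstance]:
    """Callout instances for every stay plus per-source class balancing.

    Within each source cohort, augmented NRFD instances are added until the
    NRFD count reaches the RFD count or the sampling pool is exhausted.
    A second draw from the same stay is only used when one-per-stay cannot
    balance the classes.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    dataset: list[LabeledInstance] = []
    for stays in cohorts:
        if len(stays) == 0:
            logger.warning("empty cohort; contributing no instances")
            continue
        callout = [inst for s in stays if (inst := label_at_callout(s)) is not None]
        n_rfd = sum(1 for i in callout if i.label == RFD)
        n_nrfd = len(callout) - n_rfd
        deficit = max(n_rfd - n_nrfd, 0)
        augmented = augment_negatives(stays, deficit, rng, max_per_stay=1)
        if len(augmented) < deficit and max_per_stay > 1:
            extra = augment_negatives(stays, deficit, rng, max_per_stay=max_per_stay)
            # keep the larger draw (augment_negatives restarts from scratch)
            if len(extra) > len(augmented):
                augmented = extra
        dataset.extend(callout)
        dataset.extend(augmented)
    return dataset


def instances_to_csv(instances: Iterable[LabeledInstance], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "stay_id": i.stay_id,
                "source": i.source,
                "t_ref_minutes": i.t_ref,
                "label": i.label,
                "provenance": i.provenance,
            }
            for i in instances
        ]
    ).to_csv(path, index=False)


def instances_from_csv(path: str | Path) -> list[LabeledInstance]:
    df = pd.read_csv(path)
    return [
        LabeledInstance(
            stay_id=str(r.stay_id),
            source=str(r.source),
            t_ref=int(r.t_ref_minutes),
            label=str(r.label),
            provenance=str(r.provenance),
        )
        for r in df.itertuples(index=False)
    ]
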