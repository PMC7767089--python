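"""Chlorpromazine-equivalent dosing, infratherapeutic flags, and dose bins.

Every antipsychotic regimen is re-expressed as a single chlorpromazine
mg/day value per patient (dose × equivalence factor, summed over the
patient's antipsychotics, polytherapy included). Long-acting injectables
must already be expressed as mg/day (monthly dose / interval days); a helper
is provided. Dose bins follow strict boundaries: below 300, 300–800, above
800 mg/d chlorpromazine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .kb import KnowledgeBase
from .records import Prescription

BINS = ("lt300", "mid", "gt800")
_LOW, _HIGH = 300.0, 800.0


class DosingError(ValueError):
    pass


@dataclass(frozen=True)
class DoseSummary:
    patient_id: str
    epoch: str
    cpz_total: float
    n_antipsychotics: int
    infratherapeutic_flags: frozenset[str]
    bin: str


def depot_daily_equivalent(dose_mg: float, interval_days: float) -> float:
    """mg/day equivalent of a depot administered every ``interval_days``."""
    if interval_days <= 0:
        raise DosingError("interval_days must be > 0")
    return dose_mg / interval_days


def cpz_equivalent(prescription: Prescription, kb: KnowledgeBase) -> float:
    """Chlorpromazine-equivalent mg/day of one prescription."""
    return prescription.daily_dose * kb.equivalence.factor(
        prescription.drug, prescription.route
    )


def flag_infratherapeutic(prescription: Prescription, kb: KnowledgeBase) -> bool:
    """True iff the daily dose is strictly below the minimum therapeutic dose."""
    return prescription.daily_dose < kb.thresholds.threshold(prescription.drug)


def assign_bin(cpz_total: float) -> str:
    if cpz_total < _LOW:
        return "lt300"
    if cpz_total > _HIGH:
        return "gt800"
    return "mid"


def summarize_patient(
    prescriptions: Sequence[Prescription], kb: KnowledgeBase
) -> DoseSummary:
    """Dose summary over one patient's antipsychotics in one epoch."""
    if not prescriptions:
        raise DosingError("no prescriptions to summarize")
    aps = [p for p in prescriptions if kb.profile(p.drug).antipsychotic]
    total = sum(cpz_equivalent(p, kb) for p in aps)
    flags = frozenset(p.drug for p in aps if flag_infratherapeutic(p, kb))
    return DoseSummary(
        patient_id=prescriptions[0].patient_id,
        epoch=prescriptions[0].epoch,
        cpz_total=total,
        n_antipsychotics=len({p.drug for p in aps}),
        infratherapeutic_flags=flags,
        bin=assign_bin(total),
    )


def dose_bins(summaries: Iterable[DoseSummary], epoch: str) -> dict:
    """Proportion of patients per chlorpromazine dose bin in one epoch."""
    counts = {b: 0 for b in BINS}
    n = 0
    for s in summaries:
        if s.epoch != epoch:
            continue
        counts[s.bin] += 1
        n += 1
    if n == 0:
        raise DosingError(f"no dose summaries for epoch {epoch!r}")
    out = {b: counts[b] / n for b in BINS}
    out["n"] = n
    return out


def summaries_to_frame(summaries: Sequence[DoseSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "epoch": s.epoch,
                "cpz_total": s.cpz_total,
                "n_antipsychotics": s.n_antipsychotics,
                "infratherapeutic": ";".join(sorted(s.infratherapeutic_flags)),
                "bin": s.bin,
            }
            for s in summaries
        ],
        columns=[
            "patient_id",
            "epoch",
            "cpz_total",
            "n_antipsychotics",
            "infratherapeutic",
            "bin",
        ],
    )
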