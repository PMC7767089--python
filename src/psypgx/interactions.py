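"""Shared-pathway drug–drug interactions and gene–drug conflict detection.

A drug–drug interaction is counted when two or more co-prescribed drugs are
mainly metabolized by (i.e. carry as a MAJOR pathway) the same CYP enzyme —
one interaction per enzyme regardless of how many drugs share it. Minor
pathways do not create interactions but do create gene–drug conflicts.

A gene–drug conflict is a prescription whose metabolizing enzyme has a
non-efficient phenotype in that patient: HI at CYP1A2, or PM/IM/UM at any
other gene (UM implies sub-therapeutic exposure risk). A conflict carries
plasma impact only when the enzyme is a major pathway not flagged as having
negligible influence on plasma levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .kb import GENES, KnowledgeBase
from .phenotyping import call_phenotype, effective_phenotype
from .records import PatientRecord, Prescription

SCOPES = ("all_drugs", "antipsychotics_only")


class MissingGenotypeWarning(UserWarning):
    """A conflict check was skipped because the gene was not genotyped."""


@dataclass(frozen=True)
class InteractionRecord:
    patient_id: str
    enzyme: str
    drugs: frozenset[str]
    scope: str
    epoch: str


@dataclass(frozen=True)
class GeneDrugConflict:
    patient_id: str
    drug: str
    enzyme: str
    category: str
    pathway_role: str  # major | minor
    plasma_impact: bool
    phenoconversion_involved: bool
    epoch: str


def detect_ddi(
    prescriptions: Sequence[Prescription],
    kb: KnowledgeBase,
    scope: str = "all_drugs",
) -> list[InteractionRecord]:
    """Shared-major-pathway interactions within one patient's epoch regimen.

    Emits exactly one record per enzyme carried as a major pathway by >= 2
    distinct co-prescribed drugs (within ``scope``), ordered by enzyme name.
    """
    if scope not in SCOPES:
        raise ValueError(f"bad scope {scope!r}")
    if not prescriptions:
        return []
    pid = prescriptions[0].patient_id
    epoch = prescriptions[0].epoch
    drugs = sorted({p.drug for p in prescriptions})
    if scope == "antipsychotics_only":
        drugs = [d for d in drugs if kb.profile(d).antipsychotic]
    records = []
    for enzyme in GENES:
        sharing = frozenset(d for d in drugs if enzyme in kb.profile(d).major_pathways)
        if len(sharing) >= 2:
            records.append(
                InteractionRecord(
                    patient_id=pid, enzyme=enzyme, drugs=sharing, scope=scope, epoch=epoch
                )
            )
    return records


def _non_efficient(enzyme: str, category: str) -> bool:
    if enzyme == "CYP1A2":
        return category == "HI"
    return category in ("PM", "IM", "UM")


def detect_conflicts(
    patient: PatientRecord,
    epoch: str,
    kb: KnowledgeBase,
    use_phenoconversion: bool = False,
) -> list[GeneDrugConflict]:
    """Gene–drug conflicts of one patient in one epoch.

    With ``use_phenoconversion`` the phenotype at each enzyme is the
    phenoconversion-adjusted (effective) one; otherwise genotypic. Enzymes
    without a genotype are skipped with a :class:`MissingGenotypeWarning`.
    """
    conflicts: list[GeneDrugConflict] = []
    for rx in sorted(patient.prescriptions_for(epoch), key=lambda p: p.drug):
        profile = kb.profile(rx.drug)
        for enzyme in sorted(profile.pathways):
            if enzyme not in patient.diplotypes:
                warnings.warn(
                    f"{patient.patient_id}: {enzyme} not genotyped; conflict check "
                    f"for {rx.drug} skipped",
                    MissingGenotypeWarning,
                    stacklevel=2,
                )
                continue
            geno_cat = call_phenotype(patient.diplotypes[enzyme], kb).category
            if use_phenoconversion:
                eff, _ = effective_phenotype(patient, enzyme, epoch, kb)
                category = eff.category
            else:
                category = geno_cat
            if not _non_efficient(enzyme, category):
                continue
            role = "major" if enzyme in profile.major_pathways else "minor"
            conflicts.append(
                GeneDrugConflict(
                    patient_id=patient.patient_id,
                    drug=rx.drug,
                    enzyme=enzyme,
                    category=category,
                    pathway_role=role,
                    plasma_impact=(
                        role == "major" and enzyme not in profile.negligible_plasma_effect
                    ),
                    phenoconversion_involved=use_phenoconversion and category != geno_cat,
                    epoch=epoch,
                )
            )
    # one conflict per (drug, enzyme): polytherapy duplicates collapse
    seen: dict[tuple, GeneDrugConflict] = {}
    for c in conflicts:
        seen.setdefault((c.drug, c.enzyme), c)
    return list(seen.values())


def missing_genotype_coverage(
    patients: Iterable[PatientRecord], kb: KnowledgeBase, epoch: str = "pre"
) -> pd.DataFrame:
    """Per-gene count of prescriptions whose conflict check had no genotype."""
    counts = {g: 0 for g in GENES}
    for patient in patients:
        for rx in patient.prescriptions_for(epoch):
            for enzyme in kb.profile(rx.drug).pathways:
                if enzyme not in patient.diplotypes:
                    counts[enzyme] += 1
    return pd.DataFrame(
        {"enzyme": list(counts), "skipped_checks": list(counts.values())}
    )


def aggregate_by_enzyme(records: Iterable) -> pd.DataFrame:
    """Cohort-level counts per enzyme (and epoch/scope where present).

    Accepts interaction records or conflicts; groups on the attributes each
    record type carries. Totals equal the sum of the per-enzyme parts.
    """
    rows = []
    for r in records:
        row = {"enzyme": r.enzyme, "epoch": r.epoch}
        if hasattr(r, "scope"):
            row["scope"] = r.scope
        if hasattr(r, "plasma_impact"):
            row["plasma_impact"] = r.plasma_impact
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["enzyme", "epoch", "count"])
    df = pd.DataFrame(rows)
    keys = [c for c in ("enzyme", "epoch", "scope", "plasma_impact") if c in df.columns]
    out = df.groupby(keys, sort=True).size().reset_index(name="count")
    return out


def cohort_interactions(
    patients: Iterable[PatientRecord],
    kb: KnowledgeBase,
    epoch: str,
    scope: str = "all_drugs",
) -> list[InteractionRecord]:
    records = []
    for p in patients:
        records.extend(detect_ddi(p.prescriptions_for(epoch), kb, scope=scope))
    return records


def cohort_conflicts(
    patients: Iterable[PatientRecord],
    kb: KnowledgeBase,
    epoch: str,
    use_phenoconversion: bool = False,
) -> list[GeneDrugConflict]:
    conflicts = []
    for p in patients:
        conflicts.extend(
            detect_conflicts(p, epoch, kb, use_phenoconversion=use_phenoconversion)
        )
    return conflicts


def interactions_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "enzyme": r.enzyme,
                "drugs": ";".join(sorted(r.drugs)),
                "scope": r.scope,
                "epoch": r.epoch,
            }
            for r in records
        ],
        columns=["patient_id", "enzyme", "drugs", "scope", "epoch"],
    )


def conflicts_to_frame(conflicts: Sequence[GeneDrugConflict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "drug": c.drug,
                "enzyme": c.enzyme,
                "category": c.category,
                "pathway_role": c.pathway_role,
                "plasma_impact": int(c.plasma_impact),
                "phenoconversion_involved": int(c.phenoconversion_involved),
                "epoch": c.epoch,
            }
            for c in conflicts
        ],
        columns=[
            "patient_id",
            "drug",
            "enzyme",
            "category",
            "pathway_role",
            "plasma_impact",
            "phenoconversion_involved",
            "epoch",
        ],
    )
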