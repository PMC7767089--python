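"""Patient and prescription records, and their CSV/TSV table representations.

Diplotypes are written in the compact ``GENE:*a/*b`` dialect with an optional
``x2`` copy-number suffix (gene duplication), e.g. ``CYP2D6:*1/*2x2``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .kb import GENES, KnowledgeBase, UnknownAlleleError

EPOCHS = ("pre", "post")

_DIPLO_RE = re.compile(r"^(?P<gene>CYP\w+):(?P<a>\*[\w]+)/(?P<b>\*[\w]+?)(?P<dup>x\d+)?$")


class RecordError(ValueError):
    """A patient or prescription record failed validation."""


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of star alleles at one CYP gene, plus duplication flag."""

    gene: str
    allele_a: str
    allele_b: str
    duplication: bool = False

    def __post_init__(self):
        # canonical unordered form so that a/b and b/a compare equal
        if self.allele_a > self.allele_b:
            a, b = self.allele_b, self.allele_a
            object.__setattr__(self, "allele_a", a)
            object.__setattr__(self, "allele_b", b)

    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    def validate(self, kb: KnowledgeBase) -> None:
        for allele in self.alleles():
            if (self.gene, allele) not in kb.alleles:
                raise UnknownAlleleError(self.gene, allele)


def parse_diplotype(text: str) -> Diplotype:
    """Parse ``CYP2D6:*1/*4`` or ``CYP2D6:*1/*2x2`` into a :class:`Diplotype`."""
    m = _DIPLO_RE.match(text.strip())
    if not m:
        raise RecordError(f"cannot parse diplotype string {text!r}")
    return Diplotype(
        gene=m["gene"],
        allele_a=m["a"],
        allele_b=m["b"],
        duplication=m["dup"] is not None,
    )


def format_diplotype(d: Diplotype) -> str:
    suffix = "x2" if d.duplication else ""
    return f"{d.gene}:{d.allele_a}/{d.allele_b}{suffix}"


@dataclass(frozen=True)
class Prescription:
    """One drug prescribed to one patient in one epoch (pre/post testing)."""

    patient_id: str
    drug: str
    route: str = "oral"
    daily_dose: float = 0.0
    epoch: str = "pre"
    therapeutic_class: str = "N"

    def __post_init__(self):
        object.__setattr__(self, "drug", self.drug.lower())
        if self.route not in ("oral", "IM"):
            raise RecordError(f"{self.patient_id}/{self.drug}: bad route {self.route!r}")
        if self.epoch not in EPOCHS:
            raise RecordError(f"{self.patient_id}/{self.drug}: bad epoch {self.epoch!r}")
        if not (math.isfinite(self.daily_dose) and self.daily_dose >= 0):
            raise RecordError(
                f"{self.patient_id}/{self.drug}: dose must be finite and >= 0, "
                f"got {self.daily_dose}"
            )


@dataclass
class PatientRecord:
    """Demographics, genotypes, and the pre/post prescription lists of one patient."""

    patient_id: str
    age: float = math.nan
    sex: str = ""
    diagnosis: str = ""
    smoker: bool = False
    diplotypes: dict[str, Diplotype] = field(default_factory=dict)
    prescriptions: list[Prescription] = field(default_factory=list)

    def prescriptions_for(self, epoch: str) -> list[Prescription]:
        return [p for p in self.prescriptions if p.epoch == epoch]

    def drugs_for(self, epoch: str) -> set[str]:
        return {p.drug for p in self.prescriptions_for(epoch)}

    def with_post(self, post: list[Prescription]) -> "PatientRecord":
        """Copy of the record with the post epoch replaced."""
        keep = [p for p in self.prescriptions if p.epoch == "pre"]
        return replace(self, prescriptions=keep + list(post))


# ---------------------------------------------------------------------------
# table <-> record conversion

PATIENT_COLUMNS = ["patient_id", "age", "sex", "diagnosis", "smoker"] + list(GENES)
RX_COLUMNS = ["patient_id", "drug", "route", "daily_dose", "epoch", "therapeutic_class"]


def patients_to_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row: dict = {
            "patient_id": p.patient_id,
            "age": p.age,
            "sex": p.sex,
            "diagnosis": p.diagnosis,
            "smoker": int(p.smoker),
        }
        for gene in GENES:
            d = p.diplotypes.get(gene)
            row[gene] = format_diplotype(d) if d else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def prescriptions_to_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": rx.patient_id,
            "drug": rx.drug,
            "route": rx.route,
            "daily_dose": rx.daily_dose,
            "epoch": rx.epoch,
            "therapeutic_class": rx.therapeutic_class,
        }
        for p in patients
        for rx in p.prescriptions
    ]
    return pd.DataFrame(rows, columns=RX_COLUMNS)


def records_from_frames(
    patients_df: pd.DataFrame, rx_df: pd.DataFrame
) -> list[PatientRecord]:
    """Assemble :class:`PatientRecord` objects from the two flat tables."""
    rx_by_patient: dict[str, list[Prescription]] = {}
    for row in rx_df.itertuples(index=False):
        rx = Prescription(
            patient_id=str(row.patient_id),
            drug=str(row.drug),
            route=str(row.route),
            daily_dose=float(row.daily_dose),
            epoch=str(row.epoch),
            therapeutic_class=str(getattr(row, "therapeutic_class", "N")),
        )
        rx_by_patient.setdefault(rx.patient_id, []).append(rx)

    patients = []
    for row in patients_df.itertuples(index=False):
        pid = str(row.patient_id)
        diplos = {}
        for gene in GENES:
            text = getattr(row, gene, "")
            if isinstance(text, str) and text.strip():
                diplos[gene] = parse_diplotype(text)
        patients.append(
            PatientRecord(
                patient_id=pid,
                age=float(row.age),
                sex=str(row.sex),
                diagnosis=str(row.diagnosis),
                smoker=bool(int(row.smoker)),
                diplotypes=diplos,
                prescriptions=rx_by_patient.get(pid, []),
            )
        )
    return patients
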