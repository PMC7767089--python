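from __future__ import annotations

import pytest

from psypgx import CohortSpec, PatientRecord, Prescription, load_knowledge_base, parse_diplotype
from psypgx.cohort import generate_records


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture(scope="session")
def demo_cohort(kb):
    """Fixed-seed demo cohort used by the deterministic end-to-end checks."""
    return generate_records(CohortSpec(seed=42, n_patients=200), kb)


def make_patient(
    pid: str = "P1",
    diplotypes: dict[str, str] | None = None,
    rx: list[tuple] | None = None,
    smoker: bool = False,
) -> PatientRecord:
    """Terse patient builder: diplotypes as strings, rx as (drug[, dose[, route]])."""
    prescriptions = []
    for item in rx or []:
        parts = list(item) if isinstance(item, tuple) else [item]
        drug = parts[0]
        dose = parts[1] if len(parts) > 1 else 100.0
        route = parts[2] if len(parts) > 2 else "oral"
        prescriptions.append(
            Prescription(patient_id=pid, drug=drug, route=route, daily_dose=dose, epoch="pre")
        )
    return PatientRecord(
        patient_id=pid,
        age=40,
        sex="F",
        diagnosis="F20",
        smoker=smoker,
        diplotypes={g: parse_diplotype(f"{g}:{d}") for g, d in (diplotypes or {}).items()},
        prescriptions=prescriptions,
    )
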