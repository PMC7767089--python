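"""Machine-readable pharmacogenomic knowledge base.

Holds the static domain knowledge the pipeline runs on: star-allele activity
classes per CYP gene, per-drug CYP450 metabolism profiles (major/minor
pathways, inhibition and induction flags, metabolite activity),
chlorpromazine-equivalence factors, and minimum-therapeutic-dose thresholds.

The bundled defaults live under ``psypgx/data`` as plain TSV/JSON and are
meant to be edited: equivalence factors in particular are configuration
(published consensus values), not ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

GENES: tuple[str, ...] = (
    "CYP1A2",
    "CYP2B6",
    "CYP2C9",
    "CYP2C19",
    "CYP2D6",
    "CYP3A4",
    "CYP3A5",
)

ACTIVITY_CLASSES = frozenset(
    {"normal", "reduced", "inactive", "increased_inducibility", "increased_function"}
)
INHIBITION_MODES = frozenset(
    {"substrate_inhibition", "suicide_inhibition", "cross_inhibition"}
)
METABOLITE_ACTIVITIES = frozenset({"active", "inactive", "reduced", "mixed"})
ROUTES = ("oral", "IM")

#: Star alleles every valid KB must define (the study's genotyping panel).
REQUIRED_ALLELES: dict[str, tuple[str, ...]] = {
    "CYP1A2": ("*1F",),
    "CYP2B6": ("*6",),
    "CYP2C9": ("*1", "*2", "*3"),
    "CYP2C19": ("*1", "*2", "*4", "*17"),
    "CYP2D6": (
        "*1", "*2", "*3", "*4", "*5", "*6", "*7", "*8",
        "*9", "*10", "*12", "*14", "*17", "*29", "*41", "*46",
    ),
    "CYP3A4": ("*1B",),
    "CYP3A5": ("*3C",),
}

#: Drugs with a mandatory minimum-therapeutic-dose entry.
REQUIRED_THRESHOLDS: dict[str, float] = {
    "amisulpride": 400,
    "aripiprazole": 10,
    "asenapine": 5,
    "olanzapine": 10,
    "paliperidone": 6,
    "quetiapine": 400,
    "risperidone": 2,
}


class KBError(ValueError):
    """A knowledge-base file failed validation."""


class UnknownDrugError(KeyError):
    """A drug name does not resolve in the knowledge base."""

    def __init__(self, drug: str):
        super().__init__(drug)
        self.drug = drug

    def __str__(self) -> str:  # KeyError quotes its arg; keep a real message
        return f"drug not in knowledge base: {self.drug!r}"


class UnknownAlleleError(KeyError):
    def __init__(self, gene: str, allele: str):
        super().__init__((gene, allele))
        self.gene, self.allele = gene, allele

    def __str__(self) -> str:
        return f"allele not in knowledge base: {self.gene} {self.allele}"


@dataclass(frozen=True)
class AlleleDefinition:
    """A star allele of a CYP gene with its functional activity class."""

    gene: str
    allele: str
    activity_class: str

    def __post_init__(self):
        if self.gene not in GENES:
            raise KBError(f"unknown gene {self.gene!r} (expected one of {GENES})")
        if not self.allele.startswith("*"):
            raise KBError(f"allele names must start with '*': {self.allele!r}")
        if self.activity_class not in ACTIVITY_CLASSES:
            raise KBError(
                f"{self.gene} {self.allele}: bad activity_class {self.activity_class!r}"
            )


@dataclass(frozen=True)
class DrugMetabolismProfile:
    """A drug's CYP450 metabolism: pathways, inhibition/induction, metabolite.

    ``negligible_plasma_effect`` marks pathways whose alteration has almost no
    influence on plasma levels; conflicts through them never carry plasma
    impact. ``cyp_independent`` drugs (no CYP metabolism) have empty pathway
    sets by construction.
    """

    drug: str
    major_pathways: frozenset[str] = frozenset()
    minor_pathways: frozenset[str] = frozenset()
    negligible_plasma_effect: frozenset[str] = frozenset()
    inhibits: frozenset[tuple[str, str]] = frozenset()
    induces: frozenset[str] = frozenset()
    cyp_independent: bool = False
    metabolite_activity: str = "inactive"
    antipsychotic: bool = False
    routes: tuple[str, ...] = ("oral",)
    atc: str = "N"
    typical_daily_dose: float = 0.0

    def __post_init__(self):
        if self.drug != self.drug.lower():
            raise KBError(f"drug names are lowercase: {self.drug!r}")
        for s in (self.major_pathways, self.minor_pathways, self.induces):
            for g in s:
                if g not in GENES:
                    raise KBError(f"{self.drug}: unknown gene {g!r}")
        if self.cyp_independent and (self.major_pathways or self.minor_pathways):
            raise KBError(f"{self.drug}: cyp_independent drugs must have no pathways")
        if not self.negligible_plasma_effect <= (self.major_pathways | self.minor_pathways):
            raise KBError(
                f"{self.drug}: negligible_plasma_effect must be a subset of its pathways"
            )
        for gene, mode in self.inhibits:
            if gene not in GENES or mode not in INHIBITION_MODES:
                raise KBError(f"{self.drug}: bad inhibition entry ({gene}, {mode})")
        if self.metabolite_activity not in METABOLITE_ACTIVITIES:
            raise KBError(
                f"{self.drug}: bad metabolite_activity {self.metabolite_activity!r}"
            )
        for r in self.routes:
            if r not in ROUTES:
                raise KBError(f"{self.drug}: bad route {r!r}")

    @property
    def pathways(self) -> frozenset[str]:
        return self.major_pathways | self.minor_pathways

    def inhibited_enzymes(self, modes: Iterable[str] | None = None) -> frozenset[str]:
        wanted = INHIBITION_MODES if modes is None else frozenset(modes)
        return frozenset(g for g, m in self.inhibits if m in wanted)


@dataclass(frozen=True)
class EquivalenceTable:
    """Chlorpromazine-equivalence factors, keyed by (drug, route)."""

    factors: Mapping[tuple[str, str], float]
    provenance: str = ""

    def __post_init__(self):
        for (drug, route), f in self.factors.items():
            if f <= 0:
                raise KBError(f"equivalence factor must be > 0: {drug}/{route} = {f}")
        cpz = self.factors.get(("chlorpromazine", "oral"))
        if cpz != 1.0:
            raise KBError("chlorpromazine must map to factor 1.0")

    def factor(self, drug: str, route: str = "oral") -> float:
        try:
            return self.factors[(drug, route)]
        except KeyError:
            raise KBError(
                f"no chlorpromazine-equivalence factor for {drug!r} (route {route})"
            ) from None


@dataclass(frozen=True)
class TherapeuticThresholds:
    """Minimum therapeutic daily dose (mg/d) per drug."""

    thresholds: Mapping[str, float]

    def __post_init__(self):
        for drug, t in self.thresholds.items():
            if t <= 0:
                raise KBError(f"threshold must be > 0: {drug} = {t}")
        for drug, expected in REQUIRED_THRESHOLDS.items():
            if drug not in self.thresholds:
                raise KBError(f"missing minimum-therapeutic-dose entry for {drug!r}")

    def threshold(self, drug: str) -> float:
        try:
            return self.thresholds[drug]
        except KeyError:
            raise UnknownDrugError(drug) from None


@dataclass(frozen=True)
class KnowledgeBase:
    """Validated bundle of alleles, drug profiles, equivalences, thresholds."""

    alleles: Mapping[tuple[str, str], AlleleDefinition]
    drugs: Mapping[str, DrugMetabolismProfile]
    equivalence: EquivalenceTable
    thresholds: TherapeuticThresholds

    def activity(self, gene: str, allele: str) -> str:
        try:
            return self.alleles[(gene, allele)].activity_class
        except KeyError:
            raise UnknownAlleleError(gene, allele) from None

    def alleles_of(self, gene: str) -> list[AlleleDefinition]:
        return [a for a in self.alleles.values() if a.gene == gene]

    def profile(self, drug: str) -> DrugMetabolismProfile:
        try:
            return self.drugs[drug.lower()]
        except KeyError:
            raise UnknownDrugError(drug) from None

    def antipsychotics(self) -> list[str]:
        return sorted(d for d, p in self.drugs.items() if p.antipsychotic)


# ---------------------------------------------------------------------------
# loading / serialisation


def _data_path(name: str) -> Path:
    return Path(str(resources.files("psypgx").joinpath("data", name)))


def load_alleles(path: str | Path | None = None) -> dict[tuple[str, str], AlleleDefinition]:
    """Read allele activity classes from TSV (columns gene, allele, activity_class)."""
    path = Path(path) if path else _data_path("alleles.tsv")
    if not path.exists():
        raise FileNotFoundError(f"allele table not found: {path}")
    alleles: dict[tuple[str, str], AlleleDefinition] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene", "allele", "activity_class"]:
            raise KBError(f"{path}: expected columns gene, allele, activity_class")
        for ln in fh:
            if not ln.strip():
                continue
            gene, allele, cls = ln.rstrip("\n").split("\t")[:3]
            key = (gene, allele)
            if key in alleles:
                raise KBError(f"duplicate allele definition: {gene} {allele}")
            alleles[key] = AlleleDefinition(gene, allele, cls)
    for gene, required in REQUIRED_ALLELES.items():
        for allele in required:
            if (gene, allele) not in alleles:
                raise KBError(f"allele table is missing {gene} {allele}")
    return alleles


def load_drugs(path: str | Path | None = None) -> dict[str, DrugMetabolismProfile]:
    path = Path(path) if path else _data_path("drugs.json")
    if not path.exists():
        raise FileNotFoundError(f"drug profile file not found: {path}")
    raw = json.loads(path.read_text())
    drugs: dict[str, DrugMetabolismProfile] = {}
    for name, d in raw["drugs"].items():
        name = name.lower()
        if name in drugs:
            raise KBError(f"duplicate drug profile: {name}")
        drugs[name] = DrugMetabolismProfile(
            drug=name,
            major_pathways=frozenset(d.get("major_pathways", [])),
            minor_pathways=frozenset(d.get("minor_pathways", [])),
            negligible_plasma_effect=frozenset(d.get("negligible_plasma_effect", [])),
            inhibits=frozenset((g, m) for g, m in d.get("inhibits", [])),
            induces=frozenset(d.get("induces", [])),
            cyp_independent=bool(d.get("cyp_independent", False)),
            metabolite_activity=d.get("metabolite_activity", "inactive"),
            antipsychotic=bool(d.get("antipsychotic", False)),
            routes=tuple(d.get("routes", ["oral"])),
            atc=d.get("atc", "N"),
            typical_daily_dose=float(d.get("typical_daily_dose", 0.0)),
        )
    return drugs


def load_equivalence(path: str | Path | None = None) -> EquivalenceTable:
    path = Path(path) if path else _data_path("cpz_equivalents.json")
    if not path.exists():
        raise FileNotFoundError(f"equivalence table not found: {path}")
    raw = json.loads(path.read_text())
    factors = {
        (drug.lower(), route): float(f)
        for drug, routes in raw["factors"].items()
        for route, f in routes.items()
    }
    return EquivalenceTable(factors=factors, provenance=raw.get("provenance", ""))


def load_thresholds(path: str | Path | None = None) -> TherapeuticThresholds:
    path = Path(path) if path else _data_path("thresholds.json")
    if not path.exists():
        raise FileNotFoundError(f"threshold table not found: {path}")
    raw = json.loads(path.read_text())
    return TherapeuticThresholds(
        thresholds={d.lower(): float(t) for d, t in raw["thresholds"].items()}
    )


def load_knowledge_base(
    alleles_path: str | Path | None = None,
    drugs_path: str | Path | None = None,
    equivalence_path: str | Path | None = None,
    thresholds_path: str | Path | None = None,
) -> KnowledgeBase:
    """Load and validate the full KB bundle (bundled defaults when paths omitted)."""
    return KnowledgeBase(
        alleles=load_alleles(alleles_path),
        drugs=load_drugs(drugs_path),
        equivalence=load_equivalence(equivalence_path),
        thresholds=load_thresholds(thresholds_path),
    )


def serialize_knowledge_base(kb: KnowledgeBase) -> dict:
    """Dump a KB to plain JSON-compatible structures (sorted, round-trippable)."""
    return {
        "alleles": [
            {"gene": a.gene, "allele": a.allele, "activity_class": a.activity_class}
            for a in sorted(kb.alleles.values(), key=lambda a: (a.gene, a.allele))
        ],
        "drugs": {
            name: {
                "major_pathways": sorted(p.major_pathways),
                "minor_pathways": sorted(p.minor_pathways),
                "negligible_plasma_effect": sorted(p.negligible_plasma_effect),
                "inhibits": sorted([g, m] for g, m in p.inhibits),
                "induces": sorted(p.induces),
                "cyp_independent": p.cyp_independent,
                "metabolite_activity": p.metabolite_activity,
                "antipsychotic": p.antipsychotic,
                "routes": list(p.routes),
                "atc": p.atc,
                "typical_daily_dose": p.typical_daily_dose,
            }
            for name, p in sorted(kb.drugs.items())
        },
        "equivalence": {
            "provenance": kb.equivalence.provenance,
            "factors": {
                f"{drug}|{route}": f
                for (drug, route), f in sorted(kb.equivalence.factors.items())
            },
        },
        "thresholds": dict(sorted(kb.thresholds.thresholds.items())),
    }
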