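"""Diplotype-to-phenotype translation and drug-induced phenoconversion.

Genotypic phenotypes
--------------------
A diplotype is mapped to one of five categorical metabolic phenotypes:

* ``PM``  poor metabolizer — two inactive alleles;
* ``IM``  intermediate — any mix of reduced/inactive with at most one
  fully functional allele (reduced+reduced, reduced+inactive,
  inactive+normal, reduced+normal, increased-function+inactive/reduced);
* ``EM``  extensive — two normal-function (wild-type-like) alleles;
* ``UM``  ultrarapid — a gene duplication, or an increased-function allele,
  with no inactive/reduced allele present;
* ``HI``  higher inducibility — CYP1A2 only, carriers of an allele with
  increased inducibility (e.g. CYP1A2*1F), whose activity is strongly
  induced by agents such as tobacco smoke.

The rules are applied in a fixed order (HI, then UM, then PM, then IM,
then EM); the first matching rule wins, so a CYP1A2 *1F carrier is HI even
when duplicated, and duplication never rescues inactive/reduced alleles.

Effective phenotypes (phenoconversion)
--------------------------------------
Co-medication can make a genotypic extensive metabolizer behave like a poor
metabolizer (and vice versa). On the ordered ladder PM < IM < EM < UM:

* any co-prescribed reversible inhibitor of the gene (substrate or cross
  inhibition) downgrades the category by one step — once, no matter how many
  inhibitors are present (floor PM);
* a suicide (irreversible) inhibitor downgrades directly to PM;
* any inducer upgrades by one step (cap UM), applied after downgrades;
* a smoking CYP1A2-HI patient is reported as UM-equivalent for substrate
  exposure; the stored genotypic phenotype is never mutated. HI itself sits
  outside the ladder and is not moved by prescription inhibitors/inducers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .kb import GENES, KnowledgeBase
from .records import Diplotype, PatientRecord, Prescription

CATEGORIES = ("PM", "IM", "EM", "UM", "HI")
LADDER = ("PM", "IM", "EM", "UM")  # total order used for phenoconversion steps


class PhenotypeError(ValueError):
    pass


class DuplicationSemanticsWarning(UserWarning):
    """Duplication reported for a gene without copy-number semantics."""


#: genes for which a copy-number gain has defined phenotype semantics
DUPLICATION_GENES = frozenset({"CYP2D6"})


@dataclass(frozen=True)
class MetabolicPhenotype:
    gene: str
    category: str
    basis: str = "genotypic"  # or "effective"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise PhenotypeError(f"bad category {self.category!r}")
        if self.category == "HI" and self.gene != "CYP1A2":
            raise PhenotypeError("HI is defined for CYP1A2 only")


@dataclass(frozen=True)
class PhenoconversionEvent:
    """One genotype-to-effective phenotype adjustment and its cause."""

    gene: str
    cause: str  # drug name or "tobacco"
    direction: str  # downgrade | upgrade
    mode: str  # substrate_inhibition | suicide_inhibition | cross_inhibition | induction
    from_category: str
    to_category: str


def call_phenotype(diplotype: Diplotype, kb: KnowledgeBase) -> MetabolicPhenotype:
    """Translate one diplotype into its genotypic metabolic phenotype."""
    gene = diplotype.gene
    classes = tuple(kb.activity(gene, a) for a in diplotype.alleles())

    duplication = diplotype.duplication
    if duplication and gene not in DUPLICATION_GENES and gene != "CYP1A2":
        warnings.warn(
            f"{gene}: duplication reported but gene has no copy-number semantics; "
            "treated as no duplication",
            DuplicationSemanticsWarning,
            stacklevel=2,
        )
        duplication = False

    n_inactive = classes.count("inactive")
    n_reduced = classes.count("reduced")
    has_loss = n_inactive + n_reduced > 0

    if gene == "CYP1A2" and "increased_inducibility" in classes:
        category = "HI"
    elif duplication and not has_loss:
        category = "UM"
    elif "increased_function" in classes and not has_loss:
        category = "UM"
    elif n_inactive == 2:
        category = "PM"
    elif has_loss:
        category = "IM"
    else:
        category = "EM"
    return MetabolicPhenotype(gene=gene, category=category)


def _step(category: str, delta: int) -> str:
    i = LADDER.index(category) + delta
    return LADDER[max(0, min(len(LADDER) - 1, i))]


def effective_phenotype(
    patient: PatientRecord,
    gene: str,
    epoch: str,
    kb: KnowledgeBase,
    exclude_drug: str | None = None,
) -> tuple[MetabolicPhenotype, list[PhenoconversionEvent]]:
    """Phenoconversion-adjusted phenotype of ``patient`` at ``gene``.

    ``exclude_drug`` removes one drug from the inhibitor/inducer pool, used
    when assessing that drug's own exposure (a substrate inhibitor should not
    veto itself as a therapy candidate).

    Pure function of (genotype, prescription set, smoking); returns the
    effective phenotype and the list of applied phenoconversion events.
    """
    if gene not in GENES:
        raise PhenotypeError(f"unknown gene {gene!r}")
    if gene not in patient.diplotypes:
        raise PhenotypeError(f"{patient.patient_id}: no genotype for {gene}")

    geno = call_phenotype(patient.diplotypes[gene], kb)
    events: list[PhenoconversionEvent] = []
    rx_drugs = sorted(
        {
            p.drug
            for p in patient.prescriptions_for(epoch)
            if p.drug != (exclude_drug or "").lower()
        }
    )

    if geno.category == "HI":
        # HI lies outside the PM..UM ladder; tobacco induction is reported as
        # an exposure-equivalent upgrade without changing the stored category.
        if patient.smoker:
            events.append(
                PhenoconversionEvent(
                    gene=gene,
                    cause="tobacco",
                    direction="upgrade",
                    mode="induction",
                    from_category="HI",
                    to_category="UM",
                )
            )
        return MetabolicPhenotype(gene=gene, category="HI", basis="effective"), events

    suicide = [
        d for d in rx_drugs if (gene, "suicide_inhibition") in kb.profile(d).inhibits
    ]
    reversible = [
        d
        for d in rx_drugs
        if kb.profile(d).inhibits
        & {(gene, "substrate_inhibition"), (gene, "cross_inhibition")}
    ]
    inducers = [d for d in rx_drugs if gene in kb.profile(d).induces]

    cat = geno.category
    if suicide:
        if cat != "PM":
            events.append(
                PhenoconversionEvent(
                    gene=gene,
                    cause=suicide[0],
                    direction="downgrade",
                    mode="suicide_inhibition",
                    from_category=cat,
                    to_category="PM",
                )
            )
            cat = "PM"
    elif reversible:
        new = _step(cat, -1)
        if new != cat:
            mode = (
                "substrate_inhibition"
                if (gene, "substrate_inhibition") in kb.profile(reversible[0]).inhibits
                else "cross_inhibition"
            )
            events.append(
                PhenoconversionEvent(
                    gene=gene,
                    cause=reversible[0],
                    direction="downgrade",
                    mode=mode,
                    from_category=cat,
                    to_category=new,
                )
            )
            cat = new

    if inducers:
        new = _step(cat, +1)
        if new != cat:
            events.append(
                PhenoconversionEvent(
                    gene=gene,
                    cause=inducers[0],
                    direction="upgrade",
                    mode="induction",
                    from_category=cat,
                    to_category=new,
                )
            )
            cat = new

    return MetabolicPhenotype(gene=gene, category=cat, basis="effective"), events


def genotypic_phenotypes(
    patient: PatientRecord, kb: KnowledgeBase
) -> dict[str, MetabolicPhenotype]:
    """All genotypic phenotypes computable for a patient."""
    return {g: call_phenotype(d, kb) for g, d in patient.diplotypes.items()}
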