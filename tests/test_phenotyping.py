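import itertools

import pytest

from psypgx import Diplotype, call_phenotype, effective_phenotype, parse_diplotype
from psypgx.kb import GENES
from psypgx.phenotyping import (
    LADDER,
    DuplicationSemanticsWarning,
    PhenotypeError,
)

from conftest import make_patient


def literal_rule_oracle(gene: str, cls_a: str, cls_b: str, dup: bool) -> str:
    """Independent, literal transcription of the phenotype assignment rules."""
    pair = sorted([cls_a, cls_b])
    loss = any(c in ("inactive", "reduced") for c in pair)
    if gene == "CYP1A2" and "increased_inducibility" in pair:
        return "HI"
    if dup and not loss:
        return "UM"
    if "increased_function" in pair and not loss:
        return "UM"
    if pair == ["inactive", "inactive"]:
        return "PM"
    if pair in (
        ["reduced", "reduced"],
        ["inactive", "reduced"],
        ["inactive", "normal"],
        ["normal", "reduced"],
        ["inactive", "increased_function"],
        ["increased_function", "reduced"],
    ):
        return "IM"
    return "EM"


@pytest.mark.parametrize(
    "text, expected",
    [
        ("CYP2D6:*4/*4", "PM"),
        ("CYP2D6:*1/*1", "EM"),
        ("CYP2D6:*1/*2x2", "UM"),
        ("CYP2D6:*1/*4", "IM"),
        ("CYP2D6:*41/*41", "IM"),
        ("CYP2D6:*4/*41", "IM"),
        ("CYP3A5:*3C/*3C", "PM"),
        ("CYP3A5:*1/*3C", "IM"),
        ("CYP2C19:*1/*17", "UM"),
        ("CYP2C19:*2/*17", "IM"),
        ("CYP2C19:*2/*4", "PM"),
        ("CYP3A4:*1/*1B", "IM"),
        ("CYP3A4:*1B/*1B", "PM"),
        ("CYP1A2:*1/*1F", "HI"),
        ("CYP1A2:*1/*1", "EM"),
        ("CYP2B6:*6/*6", "PM"),
        ("CYP2C9:*1/*2", "IM"),
    ],
)
def test_genotypic_phenotype_examples(kb, text, expected):
    assert call_phenotype(parse_diplotype(text), kb).category == expected


def test_exhaustive_agreement_with_literal_rules(kb):
    """Every constructible diplotype (and duplication state) matches the oracle."""
    checked = 0
    for gene in GENES:
        alleles = kb.alleles_of(gene)
        dups = (False, True) if gene == "CYP2D6" else (False,)
        for a, b in itertools.combinations_with_replacement(alleles, 2):
            for dup in dups:
                got = call_phenotype(
                    Diplotype(gene, a.allele, b.allele, duplication=dup), kb
                ).category
                want = literal_rule_oracle(gene, a.activity_class, b.activity_class, dup)
                assert got == want, (gene, a.allele, b.allele, dup)
                checked += 1
    assert checked > 150  # CYP2D6 alone contributes 16*17/2 * 2 diplotypes


def test_allele_order_symmetry(kb):
    for gene in GENES:
        alleles = [a.allele for a in kb.alleles_of(gene)]
        for x, y in itertools.permutations(alleles, 2):
            assert (
                call_phenotype(Diplotype(gene, x, y), kb).category
                == call_phenotype(Diplotype(gene, y, x), kb).category
            )


def test_duplication_without_copy_number_semantics_warns(kb):
    with pytest.warns(DuplicationSemanticsWarning):
        ph = call_phenotype(parse_diplotype("CYP2C9:*1/*1x2"), kb)
    assert ph.category == "EM"  # treated as no duplication


def test_unknown_allele_raises(kb):
    with pytest.raises(KeyError):
        call_phenotype(parse_diplotype("CYP2D6:*1/*99"), kb)


# ---------------------------------------------------------------------------
# phenoconversion


def test_single_prescription_nonsmoker_identity(kb):
    p = make_patient(diplotypes={"CYP3A4": "*1/*1"}, rx=[("quetiapine", 300)])
    # quetiapine does not inhibit or induce CYP3A4 itself
    eff, events = effective_phenotype(p, "CYP3A4", "pre", kb)
    assert eff.category == "EM"
    assert events == []


def test_coprescribed_inhibitor_downgrades_one_step(kb):
    p = make_patient(
        diplotypes={"CYP3A4": "*1/*1"},
        rx=[("quetiapine", 300), ("olanzapine", 10)],
    )
    eff, events = effective_phenotype(p, "CYP3A4", "pre", kb)
    assert eff.category == "IM"
    assert len(events) == 1
    assert events[0].cause == "olanzapine" and events[0].direction == "downgrade"


def test_multiple_inhibitors_downgrade_only_once(kb):
    p = make_patient(
        diplotypes={"CYP3A4": "*1/*1"},
        rx=[("olanzapine", 10), ("fluoxetine", 20), ("risperidone", 4)],
    )
    eff, _ = effective_phenotype(p, "CYP3A4", "pre", kb)
    assert eff.category == "IM"  # one step despite three inhibitors


def test_suicide_inhibition_goes_directly_to_pm(kb):
    p = make_patient(diplotypes={"CYP2D6": "*1/*1"}, rx=[("asenapine", 10)])
    eff, events = effective_phenotype(p, "CYP2D6", "pre", kb)
    assert eff.category == "PM"
    assert events[0].mode == "suicide_inhibition"


def test_inducer_upgrades_after_downgrades(kb):
    # carbamazepine induces CYP3A4; risperidone inhibits it
    p = make_patient(
        diplotypes={"CYP3A4": "*1/*1"},
        rx=[("carbamazepine", 800), ("risperidone", 4)],
    )
    eff, events = effective_phenotype(p, "CYP3A4", "pre", kb)
    assert eff.category == "EM"  # down one then up one
    assert [e.direction for e in events] == ["downgrade", "upgrade"]


def test_smoking_hi_reported_as_um_equivalent(kb):
    p = make_patient(diplotypes={"CYP1A2": "*1/*1F"}, rx=[("olanzapine", 10)], smoker=True)
    eff, events = effective_phenotype(p, "CYP1A2", "pre", kb)
    assert eff.category == "HI"  # stored category unchanged
    assert any(e.cause == "tobacco" and e.to_category == "UM" for e in events)


def test_nonsmoker_hi_has_no_tobacco_event(kb):
    p = make_patient(diplotypes={"CYP1A2": "*1/*1F"}, rx=[("olanzapine", 10)])
    _, events = effective_phenotype(p, "CYP1A2", "pre", kb)
    assert events == []


def test_inhibitor_monotonicity_and_idempotence(kb):
    """Adding an inhibitor never raises, adding an inducer never lowers."""
    base_rx = [("quetiapine", 300)]
    for geno in ("*1/*1", "*1/*1B", "*1B/*1B"):
        p0 = make_patient(diplotypes={"CYP3A4": geno}, rx=base_rx)
        p1 = make_patient(diplotypes={"CYP3A4": geno}, rx=base_rx + [("olanzapine", 10)])
        p2 = make_patient(diplotypes={"CYP3A4": geno}, rx=base_rx + [("carbamazepine", 800)])
        c0, _ = effective_phenotype(p0, "CYP3A4", "pre", kb)
        c1, _ = effective_phenotype(p1, "CYP3A4", "pre", kb)
        c2, _ = effective_phenotype(p2, "CYP3A4", "pre", kb)
        assert LADDER.index(c1.category) <= LADDER.index(c0.category)
        assert LADDER.index(c2.category) >= LADDER.index(c0.category)
        again, _ = effective_phenotype(p1, "CYP3A4", "pre", kb)
        assert again == c1


def test_missing_genotype_raises(kb):
    p = make_patient(rx=[("quetiapine", 300)])
    with pytest.raises(PhenotypeError, match="no genotype"):
        effective_phenotype(p, "CYP3A4", "pre", kb)
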