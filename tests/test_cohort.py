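import warnings

import numpy as np
import pytest

from psypgx.cohort import (
    AP_COUNT_PROBS,
    CohortSpec,
    CohortSpecError,
    apply_intervention,
    diplotype_distribution,
    generate,
    generate_records,
    sample_mean_matched_dose,
)
from psypgx.interactions import MissingGenotypeWarning, cohort_conflicts
from psypgx.phenotyping import call_phenotype
from psypgx.records import records_from_frames

from conftest import make_patient


def test_empty_cohort(kb):
    patients_df, rx_df = generate(CohortSpec(seed=1, n_patients=0), kb)
    assert patients_df.empty and rx_df.empty


def test_same_seed_identical_output(kb):
    a = generate(CohortSpec(seed=9, n_patients=40), kb)
    b = generate(CohortSpec(seed=9, n_patients=40), kb)
    assert a[0].to_csv() == b[0].to_csv()
    assert a[1].to_csv() == b[1].to_csv()


def test_different_seed_differs(kb):
    a = generate(CohortSpec(seed=9, n_patients=40), kb)
    b = generate(CohortSpec(seed=10, n_patients=40), kb)
    assert a[1].to_csv() != b[1].to_csv()


def test_spec_validation():
    with pytest.raises(CohortSpecError):
        CohortSpec(seed=1, n_patients=-1).validate()
    with pytest.raises(CohortSpecError):
        CohortSpec(seed=1, smoking_prevalence=1.5).validate()
    with pytest.raises(CohortSpecError):
        CohortSpec(seed=1, ap_count_probs={1: 0.5, 2: 0.4}).validate()
    with pytest.raises(CohortSpecError):
        CohortSpec(seed="not-an-int").validate()


def test_infeasible_phenotype_target_names_gene(kb):
    # CYP2B6 has no increased-function allele and no duplication semantics,
    # so an ultrarapid target cannot be realized
    with pytest.raises(CohortSpecError, match="CYP2B6"):
        diplotype_distribution("CYP2B6", {"UM": 10, "EM": 90}, kb)


def test_dose_sampler_respects_bounds_and_mean():
    rng = np.random.default_rng(3)
    lo, mean, hi = 10.0, 304.01, 1200.0
    draws = np.array([sample_mean_matched_dose(rng, lo, mean, hi) for _ in range(20000)])
    assert draws.min() >= lo and draws.max() <= hi
    assert draws.mean() == pytest.approx(mean, rel=0.02)


def test_generated_doses_within_per_drug_ranges(kb):
    spec = CohortSpec(seed=5, n_patients=150)
    _, rx_df = generate(spec, kb)
    for drug, (lo, _, hi) in spec.dose_ranges.items():
        doses = rx_df[(rx_df.drug == drug) & (rx_df.epoch == "pre")]["daily_dose"]
        if len(doses):
            assert doses.min() >= lo and doses.max() <= hi


def test_antipsychotic_count_distribution(kb):
    _, rx_df = generate(CohortSpec(seed=2, n_patients=2000), kb)
    ap_drugs = {d for d in rx_df.drug.unique() if kb.profile(d).antipsychotic}
    counts = (
        rx_df[rx_df.drug.isin(ap_drugs)].groupby("patient_id")["drug"].nunique()
    )
    assert counts.min() >= 1 and counts.max() <= 4
    target_mean = sum(k * v for k, v in AP_COUNT_PROBS.items())
    assert counts.mean() == pytest.approx(target_mean, abs=0.05)
    assert (counts > 1).mean() == pytest.approx(0.7128, abs=0.04)


def test_demographics_match_spec_in_expectation(kb):
    spec = CohortSpec(seed=4, n_patients=2000)
    patients_df, _ = generate(spec, kb)
    assert patients_df.age.between(*spec.age_bounds).all()
    assert (patients_df.sex == "F").mean() == pytest.approx(0.5957, abs=0.04)
    assert patients_df.smoker.mean() == pytest.approx(0.5138, abs=0.04)
    assert (patients_df.diagnosis == "F20").mean() == pytest.approx(126 / 186, abs=0.04)


def test_genotyped_fractions_and_roundtrip(kb):
    spec = CohortSpec(seed=6, n_patients=1000)
    patients_df, rx_df = generate(spec, kb)
    assert (patients_df.CYP3A4 != "").all()  # every patient genotyped at CYP3A4
    frac_2b6 = (patients_df.CYP2B6 != "").mean()
    assert frac_2b6 == pytest.approx(166 / 188, abs=0.04)
    # records round-trip through the flat tables
    patients = records_from_frames(patients_df, rx_df)
    assert len(patients) == 1000
    assert sum(len(p.prescriptions) for p in patients) == len(rx_df)


def test_phenotype_frequency_recovery_single_gene(kb):
    """Sanity check at n=1500: CYP1A2 HI frequency near its 86.03% target."""
    patients = generate_records(CohortSpec(seed=8, n_patients=1500), kb)
    cats = [
        call_phenotype(p.diplotypes["CYP1A2"], kb).category
        for p in patients
        if "CYP1A2" in p.diplotypes
    ]
    hi = sum(c == "HI" for c in cats) / len(cats)
    assert hi == pytest.approx(154 / 179, abs=0.03)


def test_intervention_noop_on_clean_cohort(kb):
    clean = [
        make_patient(
            f"C{i}",
            diplotypes={"CYP2D6": "*1/*1", "CYP3A4": "*1/*1"},
            rx=[("amisulpride", 400)],
        )
        for i in range(5)
    ]
    updated, recs, audit = apply_intervention(clean, kb)
    assert all(r.action == "no_change" for r in recs)
    for p in updated:
        pre = [(x.drug, x.daily_dose) for x in p.prescriptions_for("pre")]
        post = [(x.drug, x.daily_dose) for x in p.prescriptions_for("post")]
        assert pre == post


def test_intervention_switches_all_hi_olanzapine_patients(kb):
    cohort = [
        make_patient(
            f"H{i}",
            diplotypes={"CYP1A2": "*1F/*1F", "CYP2D6": "*1/*1", "CYP3A4": "*1/*1"},
            rx=[("olanzapine", 15)],
            smoker=True,
        )
        for i in range(10)
    ]
    _, recs, _ = apply_intervention(cohort, kb)
    assert all(r.action in ("switch_drug", "switch_to_depot") for r in recs)


def test_intervention_reduces_conflicts_on_demo_cohort(kb, demo_cohort):
    updated, _, audit = apply_intervention(demo_cohort, kb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingGenotypeWarning)
        pre = cohort_conflicts(updated, kb, "pre")
        post = cohort_conflicts(updated, kb, "post")
    assert len(post) < len(pre)
    assert len(audit) == len(demo_cohort)
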