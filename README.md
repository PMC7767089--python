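# psypgx

**CYP450 pharmacogenetic decision support for antipsychotic therapy.**

Antipsychotics are mostly cleared by a handful of highly polymorphic
cytochrome P450 enzymes (CYP1A2, CYP2B6, CYP2C9, CYP2C19, CYP2D6, CYP3A4,
CYP3A5). The same prescription can therefore be sub-therapeutic in one
patient and toxic in another, and co-medication can convert a genotypic
extensive metabolizer into a phenotypic poor metabolizer (phenoconversion).
`psypgx` implements a stepwise precision-medicine analysis for psychiatric
cohorts with poor response to neuroleptic treatment:

1. **Phenotyping** — star-allele diplotypes (e.g. `CYP2D6:*1/*4`) are mapped
   to categorical metabolic phenotypes. PM = two inactive alleles; IM = any
   reduced/inactive mix with at most one functional allele; EM = two
   wild-type-like alleles; UM = gene duplication or an increased-function
   allele without loss alleles; HI (CYP1A2 only) = carriers of the highly
   inducible *1F allele.
2. **Interaction screening** — two or more co-prescribed drugs mainly
   metabolized by the same enzyme count as one interaction per enzyme;
   gene–drug conflicts flag prescriptions metabolized through an altered
   pathway (with or without plasma-level impact), optionally on
   phenoconversion-adjusted phenotypes (one-step downgrade per inhibited
   enzyme, direct-to-PM for suicide inhibition, one-step upgrade per
   inducer).
3. **Therapy correction** — a deterministic ranked policy proposes switches
   (CYP-independent depot first, then drugs whose major pathways are all
   extensive for the patient), consolidation to monotherapy, or dose
   reduction to the minimum therapeutic dose.
4. **Dosing and statistics** — regimens are summed into a single
   chlorpromazine-equivalent mg/day per patient; before/after cohorts are
   compared with exact Wilcoxon signed-rank and McNemar tests, within-patient
   dose-variation summaries, dose bins (<300 / 300–800 / >800 mg/d), and a
   noncentral-t paired power calculation.

A synthetic-cohort generator reproduces the statistical structure of a
188-patient observational study (demographics, phenotype frequencies under
Hardy–Weinberg sampling, prescription mix, dose ranges) so the entire
pipeline runs and is testable without any patient-level data.

## Worked example

```python
import psypgx as px

kb = px.load_knowledge_base()          # bundled allele/drug/dose tables

patient = px.PatientRecord(
    patient_id="P001", age=52, sex="F", diagnosis="F20", smoker=True,
    diplotypes={
        "CYP1A2": px.parse_diplotype("CYP1A2:*1/*1F"),
        "CYP2D6": px.parse_diplotype("CYP2D6:*1/*1"),
        "CYP3A4": px.parse_diplotype("CYP3A4:*1/*1"),
    },
    prescriptions=[
        px.Prescription("P001", "olanzapine", "oral", 20.0, "pre"),
        px.Prescription("P001", "quetiapine", "oral", 600.0, "pre"),
    ],
)

for c in px.detect_conflicts(patient, "pre", kb, use_phenoconversion=True):
    print("conflict:", c.drug, c.enzyme, c.category,
          "plasma" if c.plasma_impact else "minor")
rec = px.recommend(patient, kb)
print("action:", rec.action, "->", rec.proposed_drug, rec.proposed_route)
```

prints

```
conflict: olanzapine CYP1A2 HI plasma
conflict: olanzapine CYP2D6 IM minor
conflict: quetiapine CYP2D6 IM minor
conflict: quetiapine CYP3A4 IM plasma
action: switch_to_depot -> paliperidone IM
```

The patient is a smoking CYP1A2 higher-inducibility carrier on olanzapine (a
CYP1A2 substrate: plasma-relevant conflict) plus quetiapine, whose CYP3A4
pathway is downgraded to IM by olanzapine's CYP3A4 inhibition; the engine
proposes switching to depot paliperidone, which bypasses CYP450 entirely.
Applying the recommendation (`px.apply_recommendation`) collapses the
regimen to paliperidone 6 mg/d, taking the chlorpromazine-equivalent load
from 1198 to 400 mg/d. The design power check
`px.paired_power(200, 1050, 188, 0.05)` returns 0.831.

## Command line

```sh
psypgx kb validate
psypgx simulate --n 188 --seed 42 --out-dir cohort/
psypgx run --seed 42 --out-dir report/          # full pipeline on a simulated cohort
psypgx run --patients cohort/patients.csv --prescriptions cohort/prescriptions.csv \
           --seed 42 --out-dir report/
```

`run` writes phenotype, interaction, conflict, recommendation and dose
tables (TSV), a JSON cohort summary, and a manifest (seed + input digests)
from which every output regenerates bit-identically.

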