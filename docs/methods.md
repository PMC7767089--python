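# Methods

## Phenotype model

Each of the seven CYP genes (CYP1A2, CYP2B6, CYP2C9, CYP2C19, CYP2D6,
CYP3A4, CYP3A5) is described by a set of star alleles, each assigned one of
five activity classes: `normal`, `reduced`, `inactive`,
`increased_function`, and `increased_inducibility` (CYP1A2 *1F). A
diplotype maps to a categorical phenotype by ordered rules, first match
wins:

1. CYP1A2 carrying at least one increased-inducibility allele → **HI**;
2. gene duplication with no inactive/reduced allele → **UM**;
3. at least one increased-function allele with no inactive/reduced allele →
   **UM**;
4. two inactive alleles → **PM**;
5. any remaining combination involving a reduced or inactive allele
   (reduced+reduced, reduced+inactive, inactive+normal, reduced+normal,
   increased-function+loss) → **IM**;
6. two normal-function alleles → **EM**.

Categorical rules are used throughout; no CPIC-style fractional activity
scores are computed, because the analysis this package implements is defined
on categories. Design choices where the category assignment was genuinely
open:

* *normal + reduced* is classified IM, continuous with the neighbouring
  listed combinations.
* CYP1A2 HI is a carrier rule (one *1F suffices). A carrier rule at typical
  *1F allele frequencies is the only reading consistent with an ~86% HI
  prevalence in a European psychiatric population.
* CYP3A4 *1B is encoded `inactive`, so heterozygotes call IM and
  homozygotes PM; this reproduces the observed PM/IM/EM split. The encoding
  lives in the editable allele table, not in code.
* CYP2C19 *17 with a loss-of-function allele calls IM
  (increased-function + inactive).
* Copy-number semantics are defined for CYP2D6 only; a duplication flag on
  any other gene raises a warning and is ignored.

## Phenoconversion

Effective (phenoconverted) phenotypes adjust the genotypic category for the
patient's co-medication on the ladder PM < IM < EM < UM:

* any reversible inhibitor of the enzyme among the prescribed drugs
  (substrate or cross inhibition) downgrades **one step, once**, regardless
  of how many inhibitors are present (floor PM);
* a suicide (irreversible) inhibitor downgrades **directly to PM**;
* any inducer upgrades one step (cap UM), applied after downgrades;
* CYP1A2 HI sits outside the ladder and is not moved by drugs; for smokers
  it is reported as UM-equivalent exposure via a tobacco-induction event.
  The stored genotypic phenotype is never mutated.

The one-step magnitude is the simplest order-preserving scheme; the
literature quantifies phenoconversion only qualitatively, and the scheme is
confined to one function (`effective_phenotype`) so alternative magnitudes
are easy to substitute. When a drug is evaluated as a *candidate therapy*,
its own inhibition flags are excluded from the pool (`exclude_drug`),
otherwise any substrate inhibitor — aripiprazole at CYP2D6, for instance —
could never be proposed, contradicting clinical practice where depot
aripiprazole is a standard solution for extensive metabolizers.

## Interactions and conflicts

A drug–drug interaction is counted per enzyme when ≥ 2 distinct
co-prescribed drugs carry it as a **major** pathway ("mainly metabolized"),
one record per enzyme regardless of the number of drugs. Minor pathways do
not create interactions but do create gene–drug conflicts: one conflict per
(drug, enzyme) whose phenotype is non-efficient — HI at CYP1A2, PM/IM/UM
elsewhere (UM counts because ultrarapid clearance risks sub-therapeutic
exposure). A conflict has *plasma impact* only through a major pathway not
flagged as having negligible influence on plasma levels.

Conflict detection defaults to genotypic phenotypes (a genotype-vs-
prescription audit); the recommendation engine uses effective phenotypes,
since correction decisions must account for the regimen actually on board.
Enzymes without a genotype are skipped with a warning and tallied in a
coverage table, mirroring panel-selective genotyping in practice.

## Therapy correction

Deterministic rules, first match wins, all ties alphabetical:

1. no conflict/interaction triggers → no change;
2. plasma-impact conflict on an antipsychotic → switch. Candidates are
   ranked CYP-independent first (depot paliperidone, then amisulpride, then
   oral paliperidone), then drugs whose major pathways are all EM for the
   patient both genotypically and effectively (depot aripiprazole
   preferred). A candidate whose pathway is untested is excluded — the
   engine does not certify what it cannot check. No candidate → explicit
   "manual review" recommendation;
3. ≥ 2 antipsychotics sharing a major pathway → consolidate to monotherapy,
   keeping the drug with the fewest conflicts;
4. conflicts only through minor/negligible pathways → reduce dose to the
   drug's minimum therapeutic dose.

Low-dose olanzapine/quetiapine add-ons (below their minimum therapeutic
dose, used as hypnotics) are exempt from consolidation by default — they are
not true antipsychotic polytherapy; the exemption is a policy toggle. The
engine only recommends; `apply_recommendation` builds the post epoch,
carrying concomitant therapy unchanged and dosing a switched-in drug at its
minimum therapeutic dose (standardized depot dosing). Applying a
recommendation never increases a patient's genotypic plasma-impact conflict
count or antipsychotic count (tested per patient on the demo cohort).

## Dosing

Chlorpromazine equivalents are dose × factor summed over the patient's
antipsychotics; factors ship as editable JSON with provenance (published
consensus means — Gardner 2010, Leucht 2014) because no single conversion
table is canonical. Long-acting injectables are expressed as mg/day
(monthly dose / interval days) before conversion; IM factors default to the
oral factor. Infratherapeutic means strictly below the minimum therapeutic
dose. Dose bins use strict boundaries: < 300, [300, 800], > 800 mg/d.

## Statistics

* `percent_change` = 100 × (after − before) / before; undefined at
  before = 0. Two *variation* conventions are implemented and labelled:
  ratio of cohort means (per-drug mean-dose variation) and mean of
  within-patient percent changes with SD and a Student-t 95% CI. The
  excluding-switches variant keeps patients on the drug in both epochs; the
  including-switches variant keeps everyone on it at baseline and scores
  discontinuation as −100%.
* Wilcoxon signed-rank: zero differences dropped, tied |d| mid-ranked.
  Exact null distribution of W⁺ for n ≤ 25 via convolution over doubled
  ranks (handles tied mid-ranks exactly); above, normal approximation with
  continuity and tie correction. Two-sided p = min(1, 2·min(cdf, sf)).
* McNemar from discordant counts (b, c): exact two-sided binomial test for
  b + c < 25, continuity-corrected chi-square ((|b−c|−1)²/(b+c)) above.
* Paired power via the noncentral t distribution; sidedness is an argument,
  defaulting to one-sided (the design hypothesis — dose *reduction* — is
  directional; the two-sided value is available from the same function).
  With δ = 200 mg/d, σ = 1050 mg/d, n = 188, α = 0.05 the one-sided power
  is 0.831.
* p-values are reported without multiplicity correction, and the report
  notes this.

## Synthetic cohort generator

Defaults encode the study conditions: 188 patients; 59.57% female; age
normal(47.21, 12.93) truncated to [16, 90]; 51.38% smokers; the observed
DSM-V diagnosis mix (67% schizophrenia); per-gene genotyping coverage
(166/188 … 188/188); 1–4 antipsychotics per patient with the distribution
(0.2872, 0.6356, 0.0472, 0.0300) over 1–4, chosen to match simultaneously
the mean of 1.82 and the 71.28% polytherapy rate; the observed antipsychotic
presentation mix as sampling weights; about a quarter of polytherapy
regimens include a sub-therapeutic olanzapine/quetiapine hypnotic add-on;
concomitant medication count negative-binomial with mean 1.85.

Genotypes: for each gene, activity-class frequencies are fitted under
Hardy–Weinberg equilibrium to the target phenotype frequencies by least
squares (Nelder–Mead on logits; a duplication rate is co-fitted for
CYP2D6), then the class-pair distribution is rescaled so each phenotype
category's probability equals its target *exactly*, keeping the
within-category composition Hardy–Weinberg proportional. Pure least-squares
leaves a small residual (≈ 0.9 pp on CYP2B6 IM) that would bias frequency
recovery; the rescaling removes it while staying as close to HW as the
targets allow. Targets are the printed per-gene category *counts*
normalized by their sum — two printed percentages are internally
inconsistent with their counts and the counts are taken as authoritative.
A target category no constructible diplotype can produce raises an error
naming the gene. Within a class, specific star alleles are drawn with
realistic European-like weights (e.g. *4 dominates inactive CYP2D6).

Doses are two-piece uniform on the observed [min, max] with expectation
equal to the observed mean (only min/mean/max are known; the shape is a
pluggable choice).

What the generator does **not** emulate: correlation between genotype and
prescription (real prescribing already reacts to clinic lore),
drug-specific concomitant-therapy patterns, dose titration histories,
dropout, or longitudinal epochs beyond a single pre/post pair.
Consequently, passing tests demonstrate internal correctness of every
counting and correction rule and the recoverability of the configured
frequencies — not that real-cohort effect sizes (e.g. the ~50% mean-dose
reduction reported for real patients) are reproduced; the simulated
reductions are smaller because standardized switch doses land mid-range.

## Numerical and interface choices

* All randomness flows from one `numpy` `default_rng(seed)`; same seed ⇒
  byte-identical tables, reports, and manifest (tested).
* Display rounding is half-up to two decimals, matching hand-rounded
  tables; raw values are retained internally and in JSON reports.
* Diplotype strings use `GENE:*a/*b` with an `x2` suffix for duplication;
  alleles are stored unordered (canonical sorted form).
* Drug names are lowercase ASCII; route (oral/IM) is a separate field, so
  the same molecule's presentations are distinguished without name mangling.
* Exit codes of the CLI: 0 success, 2 validation error, 3 data error.

## Known limitations

* The knowledge base is a static snapshot (no live PharmGKB/PharmVar
  queries); concomitant-drug profiles are a small curated supplement, and
  anything absent raises a typed error rather than being ignored.
* No pharmacokinetic modelling: detection and correction are categorical.
* Dose-reduction recommendations target the minimum therapeutic dose; no
  titration schedule is produced.
* Phenoconversion magnitudes (one step; suicide inhibition → PM) are a
  modelling convention, configurable but not patient-calibrated.
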