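"""Synthetic patient-cohort generation with realistic study structure.

Generates cohorts whose demographics (age, sex, diagnosis mix, smoking),
per-gene metabolic-phenotype frequencies, antipsychotic prescription mix and
dose ranges mirror the observational cohort the analysis was designed for:
188 psychiatric patients with poor response to neuroleptic therapy, 1.82
antipsychotics per patient on average (range 1-4), 86% CYP1A2
higher-inducibility carriers, 85% CYP3A5 poor metabolizers, and so on.

Genotypes are sampled per gene from a diplotype distribution constructed in
two stages: allele-class frequencies are first fitted under Hardy-Weinberg
equilibrium to the target phenotype frequencies (least squares), then the
class-pair distribution is reweighted so that each phenotype category's
total probability equals its target exactly (the within-category composition
stays Hardy-Weinberg proportional). The phenotype caller itself maps each
class pair to its category, so generator and caller can never disagree.

Doses are drawn from a two-piece uniform on [min, max] whose expectation
equals the target mean. All sampling is driven by a single mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .kb import GENES, KnowledgeBase
from .phenotyping import call_phenotype
from .records import Diplotype, PatientRecord, Prescription
from .recommend import (
    Policy,
    Recommendation,
    apply_recommendation,
    recommend,
    recommendations_to_frame,
)


class CohortSpecError(ValueError):
    pass


STUDY_N = 188

#: observed phenotype counts per gene (the sampling targets)
PHENOTYPE_COUNTS: dict[str, dict[str, int]] = {
    "CYP1A2": {"EM": 25, "HI": 154},
    "CYP2B6": {"PM": 15, "IM": 68, "EM": 83},
    "CYP2C9": {"PM": 13, "IM": 65, "EM": 105},
    "CYP2C19": {"PM": 6, "IM": 38, "EM": 89, "UM": 52},
    "CYP2D6": {"PM": 7, "IM": 11, "EM": 159, "UM": 6},
    "CYP3A4": {"PM": 2, "IM": 14, "EM": 172},
    "CYP3A5": {"PM": 159, "IM": 25, "EM": 3},
}

#: patients genotyped per gene out of the 188 (testing was panel-selective)
GENOTYPED_N: dict[str, int] = {
    "CYP1A2": 179,
    "CYP2B6": 166,
    "CYP2C9": 183,
    "CYP2C19": 186,
    "CYP2D6": 183,
    "CYP3A4": 188,
    "CYP3A5": 187,
}

DIAGNOSIS_COUNTS: dict[str, int] = {
    "F03": 1, "F19": 12, "F20": 126, "F22": 2, "F23": 1, "F25": 13,
    "F31": 25, "F33": 1, "F60": 2, "F61": 1, "F79": 2,
}

#: antipsychotic presentation mix, pre-testing prescription counts
PRESENTATION_COUNTS: dict[tuple[str, str], int] = {
    ("amisulpride", "oral"): 14,
    ("aripiprazole", "oral"): 38,
    ("aripiprazole", "IM"): 13,
    ("asenapine", "oral"): 20,
    ("olanzapine", "oral"): 56,
    ("paliperidone", "oral"): 18,
    ("paliperidone", "IM"): 23,
    ("quetiapine", "oral"): 71,
    ("risperidone", "oral"): 44,
    ("risperidone", "IM"): 5,
}

#: per-drug (min, mean, max) daily dose mg/d observed before intervention
DOSE_RANGES: dict[str, tuple[float, float, float]] = {
    "olanzapine": (2.5, 16.38, 45),
    "aripiprazole": (3, 14.79, 30),
    "risperidone": (1, 5.39, 28.33),
    "amisulpride": (100, 514.29, 1000),
    "clozapine": (100, 325, 700),
    "paliperidone": (3, 7.08, 14),
    "quetiapine": (10, 304.01, 1200),
    "asenapine": (5, 11.75, 20),
}

#: within-activity-class star-allele weights (European-like defaults);
#: classes absent here are sampled uniformly
ALLELE_WEIGHTS: dict[tuple[str, str], dict[str, float]] = {
    ("CYP2D6", "normal"): {"*1": 0.60, "*2": 0.40},
    ("CYP2D6", "inactive"): {
        "*4": 0.72, "*5": 0.12, "*3": 0.06, "*6": 0.04, "*7": 0.02, "*8": 0.02,
        "*12": 0.02,
    },
    ("CYP2D6", "reduced"): {
        "*41": 0.50, "*10": 0.15, "*9": 0.10, "*17": 0.10, "*29": 0.05,
        "*14": 0.05, "*46": 0.05,
    },
    ("CYP2C19", "inactive"): {"*2": 0.85, "*4": 0.15},
}

#: mean antipsychotics/patient 1.82 with 71.28% of patients on more than one
AP_COUNT_PROBS: dict[int, float] = {1: 0.2872, 2: 0.6356, 3: 0.0472, 4: 0.0300}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort (defaults are the study conditions)."""

    seed: int
    n_patients: int = STUDY_N
    female_proportion: float = 0.5957
    smoking_prevalence: float = 0.5138
    age_mean: float = 47.21
    age_sd: float = 12.93
    age_bounds: tuple[float, float] = (16.0, 90.0)
    diagnosis_counts: dict[str, int] = field(default_factory=lambda: dict(DIAGNOSIS_COUNTS))
    phenotype_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {g: dict(v) for g, v in PHENOTYPE_COUNTS.items()}
    )
    genotyped_fraction: dict[str, float] = field(
        default_factory=lambda: {g: GENOTYPED_N[g] / STUDY_N for g in GENES}
    )
    ap_count_probs: dict[int, float] = field(default_factory=lambda: dict(AP_COUNT_PROBS))
    presentation_counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(PRESENTATION_COUNTS)
    )
    dose_ranges: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DOSE_RANGES)
    )
    hypnotic_addon_rate: float = 0.25
    concomitant_mean: float = 1.85
    concomitant_dispersion: float = 1.3  # negative-binomial shape (smaller = wider)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise CohortSpecError("n_patients must be >= 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise CohortSpecError("seed is mandatory and must be an integer")
        for name, p in (
            ("female_proportion", self.female_proportion),
            ("smoking_prevalence", self.smoking_prevalence),
            ("hypnotic_addon_rate", self.hypnotic_addon_rate),
        ):
            if not 0 <= p <= 1:
                raise CohortSpecError(f"{name} must be in [0, 1]")
        if abs(sum(self.ap_count_probs.values()) - 1.0) > 1e-9:
            raise CohortSpecError("ap_count_probs must sum to 1")
        for g, frac in self.genotyped_fraction.items():
            if not 0 <= frac <= 1:
                raise CohortSpecError(f"genotyped_fraction[{g}] must be in [0, 1]")
        lo, hi = self.age_bounds
        if not lo < hi:
            raise CohortSpecError("age_bounds must be increasing")


# ---------------------------------------------------------------------------
# genotype sampling


def _class_pair_category(
    gene: str, cls_a: str, cls_b: str, dup: bool, kb: KnowledgeBase
) -> str:
    """Phenotype category of a diplotype identified only by activity classes."""
    rep = {a.activity_class: a.allele for a in sorted(
        kb.alleles_of(gene), key=lambda a: a.allele)}
    d = Diplotype(gene, rep[cls_a], rep[cls_b], duplication=dup)
    return call_phenotype(d, kb).category


def diplotype_distribution(
    gene: str,
    target_counts: dict[str, int],
    kb: KnowledgeBase,
) -> list[tuple[tuple[str, str, bool], float]]:
    """Sampling distribution over (class_a, class_b, duplication) cells.

    Stage 1 fits Hardy-Weinberg class frequencies (and a duplication rate for
    genes with copy-number semantics) to the target phenotype frequencies by
    least squares; stage 2 rescales each phenotype category's cells so its
    total probability matches the target exactly.

    Raises :class:`CohortSpecError` when a target category cannot be realized
    by any diplotype constructible for the gene.
    """
    total = sum(target_counts.values())
    targets = {cat: n / total for cat, n in target_counts.items() if n > 0}
    classes = sorted({a.activity_class for a in kb.alleles_of(gene)})
    k = len(classes)
    allow_dup = gene == "CYP2D6"

    def cells_for(freqs: np.ndarray, dup_rate: float):
        cells = []
        for i in range(k):
            for j in range(i, k):
                hw = freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j]
                if allow_dup:
                    cells.append(((classes[i], classes[j], True), hw * dup_rate))
                    cells.append(((classes[i], classes[j], False), hw * (1 - dup_rate)))
                else:
                    cells.append(((classes[i], classes[j], False), hw))
        return cells

    cat_of = {
        (ca, cb, dup): _class_pair_category(gene, ca, cb, dup, kb)
        for ca in classes
        for cb in classes
        for dup in ((False, True) if allow_dup else (False,))
    }

    # feasibility is structural: some constructible diplotype must yield the
    # category, independent of the fitted frequencies
    realizable = set(cat_of.values())
    for cat in targets:
        if cat not in realizable:
            raise CohortSpecError(
                f"{gene}: phenotype target {cat!r} cannot be realized by any "
                "constructible diplotype"
            )

    def unpack(params: np.ndarray) -> tuple[np.ndarray, float]:
        logits = np.clip(params[:k], -30, 30)
        f = np.exp(logits - logits.max())
        f = np.clip(f / f.sum(), 1e-6, None)
        f = f / f.sum()
        dup_rate = float(special.expit(np.clip(params[k], -12, 12))) if allow_dup else 0.0
        return f, dup_rate

    def objective(params: np.ndarray) -> float:
        f, dup_rate = unpack(params)
        probs: dict[str, float] = {}
        for cell, p in cells_for(f, dup_rate):
            probs[cat_of[cell]] = probs.get(cat_of[cell], 0.0) + p
        cats = set(targets) | set(probs)
        return sum((probs.get(c, 0.0) - targets.get(c, 0.0)) ** 2 for c in cats)

    x0 = np.zeros(k + (1 if allow_dup else 0))
    if allow_dup:
        x0[k] = -3.0  # duplications are rare a priori
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    f, dup_rate = unpack(res.x)
    if allow_dup:
        dup_rate = min(max(dup_rate, 1e-4), 1 - 1e-4)

    cells = cells_for(f, dup_rate)
    mass: dict[str, float] = {}
    for cell, p in cells:
        mass[cat_of[cell]] = mass.get(cat_of[cell], 0.0) + p
    # exact reweighting: scale each category's cells to the target mass
    out = []
    for cell, p in cells:
        cat = cat_of[cell]
        scaled = p * targets.get(cat, 0.0) / mass[cat] if cat in targets else 0.0
        if scaled > 0:
            out.append((cell, scaled))
    norm = sum(p for _, p in out)
    return [(cell, p / norm) for cell, p in out]


class _GenotypeSampler:
    def __init__(self, kb: KnowledgeBase, spec: CohortSpec):
        self.kb = kb
        self.cells: dict[str, list[tuple[tuple[str, str, bool], float]]] = {}
        self.alleles_by_class: dict[str, dict[str, tuple[list[str], np.ndarray]]] = {}
        for gene, counts in spec.phenotype_counts.items():
            self.cells[gene] = diplotype_distribution(gene, counts, kb)
            by_class: dict[str, tuple[list[str], np.ndarray]] = {}
            for cls in {a.activity_class for a in kb.alleles_of(gene)}:
                names = sorted(
                    a.allele for a in kb.alleles_of(gene) if a.activity_class == cls
                )
                weights = ALLELE_WEIGHTS.get((gene, cls))
                w = np.array(
                    [weights.get(n, 0.0) for n in names] if weights else [1.0] * len(names)
                )
                by_class[cls] = (names, w / w.sum())
            self.alleles_by_class[gene] = by_class

    def sample(self, gene: str, rng: np.random.Generator) -> Diplotype:
        cells = self.cells[gene]
        probs = np.array([p for _, p in cells])
        idx = rng.choice(len(cells), p=probs)
        (cls_a, cls_b, dup), _ = cells[idx]
        names_a, w_a = self.alleles_by_class[gene][cls_a]
        names_b, w_b = self.alleles_by_class[gene][cls_b]
        return Diplotype(
            gene,
            names_a[rng.choice(len(names_a), p=w_a)],
            names_b[rng.choice(len(names_b), p=w_b)],
            duplication=dup,
        )


# ---------------------------------------------------------------------------
# dose & regimen sampling


def sample_mean_matched_dose(
    rng: np.random.Generator, lo: float, mean: float, hi: float
) -> float:
    """Two-piece uniform on [lo, hi] with expectation exactly ``mean``."""
    if not lo < mean < hi:
        return float(rng.uniform(lo, hi)) if lo < hi else float(lo)
    w = (hi - mean) / (hi - lo)
    if rng.random() < w:
        return float(rng.uniform(lo, mean))
    return float(rng.uniform(mean, hi))


def generate(spec: CohortSpec, kb: KnowledgeBase) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patients, prescriptions) tables; byte-reproducible per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.n_patients == 0:
        from .records import PATIENT_COLUMNS, RX_COLUMNS

        return pd.DataFrame(columns=PATIENT_COLUMNS), pd.DataFrame(columns=RX_COLUMNS)

    sampler = _GenotypeSampler(kb, spec)
    diagnoses = sorted(spec.diagnosis_counts)
    diag_w = np.array([spec.diagnosis_counts[d] for d in diagnoses], dtype=float)
    diag_w /= diag_w.sum()
    ap_counts = sorted(spec.ap_count_probs)
    ap_w = np.array([spec.ap_count_probs[c] for c in ap_counts])
    presentations = sorted(spec.presentation_counts)
    pres_w = np.array([spec.presentation_counts[p] for p in presentations], dtype=float)
    concomitants = sorted(
        d for d, p in kb.drugs.items() if not p.antipsychotic
    )
    nb_n = spec.concomitant_dispersion
    nb_p = nb_n / (nb_n + spec.concomitant_mean)

    patients: list[PatientRecord] = []
    width = max(4, len(str(spec.n_patients)))
    for i in range(spec.n_patients):
        pid = f"P{i + 1:0{width}d}"
        sex = "F" if rng.random() < spec.female_proportion else "M"
        lo, hi = spec.age_bounds
        while True:
            age = rng.normal(spec.age_mean, spec.age_sd)
            if lo <= age <= hi:
                break
        diagnosis = diagnoses[rng.choice(len(diagnoses), p=diag_w)]
        smoker = bool(rng.random() < spec.smoking_prevalence)

        diplos = {}
        for gene in GENES:
            if gene in sampler.cells and rng.random() < spec.genotyped_fraction.get(gene, 1.0):
                diplos[gene] = sampler.sample(gene, rng)

        n_ap = ap_counts[rng.choice(len(ap_counts), p=ap_w)]
        chosen: list[tuple[str, str]] = []
        used_molecules: set[str] = set()
        hypnotic_slot = n_ap >= 2 and rng.random() < spec.hypnotic_addon_rate
        if hypnotic_slot:
            drug = "olanzapine" if rng.random() < 0.5 else "quetiapine"
            chosen.append((drug, "oral"))
            used_molecules.add(drug)
        while len(chosen) < n_ap:
            avail = [
                j for j, (d, _) in enumerate(presentations) if d not in used_molecules
            ]
            w = pres_w[avail] / pres_w[avail].sum()
            j = avail[rng.choice(len(avail), p=w)]
            drug, route = presentations[j]
            chosen.append((drug, route))
            used_molecules.add(drug)

        rx: list[Prescription] = []
        for slot, (drug, route) in enumerate(chosen):
            lo_d, mean_d, hi_d = spec.dose_ranges.get(
                drug, (kb.profile(drug).typical_daily_dose,) * 3
            )
            if hypnotic_slot and slot == 0:
                # low-dose hypnotic add-on: strictly below therapeutic threshold
                thr = kb.thresholds.threshold(drug)
                dose = float(rng.uniform(lo_d, min(thr, hi_d)))
            else:
                dose = sample_mean_matched_dose(rng, lo_d, mean_d, hi_d)
            rx.append(
                Prescription(
                    patient_id=pid,
                    drug=drug,
                    route=route,
                    daily_dose=round(dose, 1),
                    epoch="pre",
                    therapeutic_class=kb.profile(drug).atc,
                )
            )

        n_con = int(rng.negative_binomial(nb_n, nb_p))
        n_con = min(n_con, len(concomitants))
        for j in rng.choice(len(concomitants), size=n_con, replace=False):
            drug = concomitants[j]
            rx.append(
                Prescription(
                    patient_id=pid,
                    drug=drug,
                    route="oral",
                    daily_dose=kb.profile(drug).typical_daily_dose,
                    epoch="pre",
                    therapeutic_class=kb.profile(drug).atc,
                )
            )

        patients.append(
            PatientRecord(
                patient_id=pid,
                age=round(float(age), 1),
                sex=sex,
                diagnosis=diagnosis,
                smoker=smoker,
                diplotypes=diplos,
                prescriptions=rx,
            )
        )

    from .records import patients_to_frame, prescriptions_to_frame

    return patients_to_frame(patients), prescriptions_to_frame(patients)


def generate_records(spec: CohortSpec, kb: KnowledgeBase) -> list[PatientRecord]:
    from .records import records_from_frames

    patients_df, rx_df = generate(spec, kb)
    return records_from_frames(patients_df, rx_df)


def apply_intervention(
    patients: list[PatientRecord],
    kb: KnowledgeBase,
    policy: Policy = Policy(),
    seed: int | None = None,
) -> tuple[list[PatientRecord], list[Recommendation], pd.DataFrame]:
    """Run the correction engine on every patient and build the post epoch.

    The engine is deterministic, so ``seed`` is accepted only for interface
    symmetry with stochastic policies. Returns the updated records, the
    recommendations, and an audit table linking each change to its triggers.
    """
    updated, recs = [], []
    for p in patients:
        rec = recommend(p, kb, epoch="pre", policy=policy)
        post = apply_recommendation(p, rec, kb, policy=policy)
        updated.append(p.with_post(post))
        recs.append(rec)
    return updated, recs, recommendations_to_frame(recs)
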