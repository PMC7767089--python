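"""Rule-based therapy correction (pharmacotherapy adjustment step).

Flags problematic regimens — a prescribed drug metabolized by an enzyme with
an inefficient (effective) phenotype, a shared-pathway interaction with
plasma-level impact, or a potential phenoconversion effect — and proposes a
deterministic correction:

1. no triggers -> ``no_change``;
2. a plasma-impact conflict on an antipsychotic -> switch, with candidates
   ranked: CYP-independent drugs first (paliperidone depot preferred), then
   drugs whose major pathways are all extensive-metabolizer for the patient
   (aripiprazole depot preferred), ties alphabetical; depot candidates yield
   ``switch_to_depot``, oral ones ``switch_drug``;
3. two or more antipsychotics sharing a major pathway -> consolidate to
   monotherapy, keeping the least-conflicted drug;
4. conflicts only through minor/negligible pathways -> ``reduce_dose`` to the
   drug's minimum therapeutic dose.

Low-dose hypnotic add-ons (olanzapine/quetiapine below their minimum
therapeutic dose) are by default exempt from consolidation — they are not
true antipsychotic polytherapy. The engine only recommends; an explicit
apply step produces the post-intervention regimen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .kb import KnowledgeBase
from .phenotyping import call_phenotype, effective_phenotype
from .interactions import MissingGenotypeWarning, detect_conflicts, detect_ddi
from .records import PatientRecord, Prescription


def _conflicts_quiet(patient, epoch, kb, use_phenoconversion):
    # genotype coverage is reported by the interaction engine; the engine
    # here only needs the conflicts that are computable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingGenotypeWarning)
        return detect_conflicts(
            patient, epoch, kb, use_phenoconversion=use_phenoconversion
        )

ACTIONS = (
    "no_change",
    "reduce_dose",
    "switch_drug",
    "consolidate_to_monotherapy",
    "switch_to_depot",
)

HYPNOTIC_ADDONS = frozenset({"olanzapine", "quetiapine"})


@dataclass(frozen=True)
class Policy:
    """Configurable ranked preferences of the correction engine."""

    hypnotic_exemption: bool = True
    prefer_depot: tuple[str, ...] = ("paliperidone", "aripiprazole")
    use_phenoconversion: bool = True


@dataclass(frozen=True)
class Recommendation:
    patient_id: str
    triggers: tuple[str, ...]
    action: str
    proposed_drug: str | None = None
    proposed_route: str | None = None
    rationale: str = ""

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise ValueError(f"bad action {self.action!r}")
        if self.action != "no_change" and not self.triggers:
            raise ValueError("a non-trivial action requires at least one trigger")


def _hypnotic_exempt(rx: Prescription, kb: KnowledgeBase) -> bool:
    return (
        rx.drug in HYPNOTIC_ADDONS
        and rx.daily_dose < kb.thresholds.threshold(rx.drug)
    )


def _is_em_everywhere(
    patient: PatientRecord,
    candidate: str,
    keep_rx: list[Prescription],
    epoch: str,
    kb: KnowledgeBase,
) -> bool:
    """Candidate's major pathways must be EM both genotypically and effectively.

    Effective phenotypes are computed against the regimen that would remain
    after the switch, excluding the candidate's own inhibition flags (a drug
    does not veto itself).
    """
    profile = kb.profile(candidate)
    if profile.cyp_independent:
        return True
    hypothetical = replace(patient, prescriptions=keep_rx)
    for gene in sorted(profile.major_pathways):
        if gene not in patient.diplotypes:
            return False  # cannot certify an untested pathway
        if call_phenotype(patient.diplotypes[gene], kb).category != "EM":
            return False
        eff, _ = effective_phenotype(hypothetical, gene, epoch, kb, exclude_drug=candidate)
        if eff.category != "EM":
            return False
    return True


def rank_candidates(
    patient: PatientRecord,
    epoch: str,
    kb: KnowledgeBase,
    exclude: frozenset[str] = frozenset(),
    policy: Policy = Policy(),
) -> list[tuple[str, str]]:
    """Ranked (drug, route) switch candidates for a patient."""
    keep_rx = [
        p for p in patient.prescriptions_for(epoch) if p.drug not in exclude
    ]

    def preferred_route(drug: str) -> str:
        return "IM" if "IM" in kb.profile(drug).routes else "oral"

    pool = [d for d in kb.antipsychotics() if d not in exclude]
    independents = [d for d in pool if kb.profile(d).cyp_independent]
    metabolized = [d for d in pool if not kb.profile(d).cyp_independent]

    def sort_group(drugs: list[str]) -> list[str]:
        # depot-capable preferred drugs first (in policy order), then alphabetical
        pref = [d for d in policy.prefer_depot if d in drugs]
        rest = sorted(d for d in drugs if d not in pref)
        return pref + rest

    ranked: list[tuple[str, str]] = []
    for d in sort_group(independents):
        ranked.append((d, preferred_route(d)))
    for d in sort_group(metabolized):
        if _is_em_everywhere(patient, d, keep_rx, epoch, kb):
            ranked.append((d, preferred_route(d)))
    return ranked


def recommend(
    patient: PatientRecord,
    kb: KnowledgeBase,
    epoch: str = "pre",
    policy: Policy = Policy(),
) -> Recommendation:
    """Deterministic therapy-correction proposal for one patient."""
    rx = patient.prescriptions_for(epoch)
    pid = patient.patient_id
    if not rx:
        return Recommendation(pid, (), "no_change", rationale="no prescriptions")

    conflicts = _conflicts_quiet(patient, epoch, kb, policy.use_phenoconversion)
    ddis = detect_ddi(rx, kb, scope="antipsychotics_only")
    events = []
    for gene in sorted(patient.diplotypes):
        _, ev = effective_phenotype(patient, gene, epoch, kb)
        events.extend(ev)

    triggers = tuple(
        [f"conflict:{c.drug}@{c.enzyme}:{c.category}" for c in conflicts]
        + [f"interaction:{r.enzyme}:" + "+".join(sorted(r.drugs)) for r in ddis]
        + [f"phenoconversion:{e.gene}:{e.cause}:{e.direction}" for e in events]
    )
    if not conflicts and not ddis:
        return Recommendation(
            pid, triggers, "no_change", rationale="no conflict or interaction triggers"
        )

    ap_conflicts = [c for c in conflicts if kb.profile(c.drug).antipsychotic]
    plasma = [c for c in ap_conflicts if c.plasma_impact]

    if plasma:
        conflicted = frozenset(c.drug for c in plasma)
        candidates = rank_candidates(patient, epoch, kb, exclude=conflicted, policy=policy)
        if not candidates:
            return Recommendation(
                pid,
                triggers,
                "switch_drug",
                rationale=(
                    "plasma-impact conflict on "
                    + ", ".join(sorted(conflicted))
                    + "; no safe candidate in knowledge base: manual review"
                ),
            )
        drug, route = candidates[0]
        return Recommendation(
            pid,
            triggers,
            "switch_to_depot" if route == "IM" else "switch_drug",
            proposed_drug=drug,
            proposed_route=route,
            rationale=(
                "plasma-impact conflict on "
                + ", ".join(sorted(conflicted))
                + f"; switch to {drug} ({route})"
            ),
        )

    # consolidation: >= 2 antipsychotics sharing a major pathway, hypnotic
    # add-ons exempt when the policy says so
    if ddis:
        if policy.hypnotic_exemption:
            core_rx = [p for p in rx if not _hypnotic_exempt(p, kb)]
            effective_ddis = detect_ddi(core_rx, kb, scope="antipsychotics_only")
        else:
            effective_ddis = ddis
        if effective_ddis:
            involved = sorted(set().union(*(r.drugs for r in effective_ddis)))
            per_drug = {
                d: sum(1 for c in ap_conflicts if c.drug == d) for d in involved
            }
            keep = min(involved, key=lambda d: (per_drug[d], d))
            return Recommendation(
                pid,
                triggers,
                "consolidate_to_monotherapy",
                proposed_drug=keep,
                rationale=(
                    "shared-pathway antipsychotic interaction ("
                    + ", ".join(involved)
                    + f"); consolidate keeping {keep}"
                ),
            )

    if ap_conflicts:  # only minor/negligible-pathway conflicts remain
        drugs = sorted({c.drug for c in ap_conflicts})
        targets = ", ".join(
            f"{d}->{kb.thresholds.thresholds.get(d, 'current')} mg/d" for d in drugs
        )
        return Recommendation(
            pid,
            triggers,
            "reduce_dose",
            rationale=f"minor-pathway conflict on {', '.join(drugs)}; reduce to {targets}",
        )

    return Recommendation(
        pid, triggers, "no_change", rationale="triggers without antipsychotic impact"
    )


def apply_recommendation(
    patient: PatientRecord,
    rec: Recommendation,
    kb: KnowledgeBase,
    policy: Policy = Policy(),
) -> list[Prescription]:
    """Produce the post-epoch prescription list a recommendation implies.

    Never mutates the patient record. Concomitant (non-antipsychotic)
    prescriptions are carried over unchanged.
    """
    pre = patient.prescriptions_for("pre")

    def as_post(p: Prescription, dose: float | None = None) -> Prescription:
        return replace(p, epoch="post", daily_dose=p.daily_dose if dose is None else dose)

    if rec.action == "no_change":
        return [as_post(p) for p in pre]

    if rec.action in ("switch_drug", "switch_to_depot"):
        conflicts = _conflicts_quiet(patient, "pre", kb, policy.use_phenoconversion)
        conflicted = {
            c.drug
            for c in conflicts
            if c.plasma_impact and kb.profile(c.drug).antipsychotic
        }
        if rec.proposed_drug is None:  # manual review: leave regimen untouched
            return [as_post(p) for p in pre]
        post = [as_post(p) for p in pre if p.drug not in conflicted]
        if any(p.drug == rec.proposed_drug for p in post):
            return post  # already on the proposed drug; dropping conflicts suffices
        dose = kb.thresholds.thresholds.get(
            rec.proposed_drug, kb.profile(rec.proposed_drug).typical_daily_dose
        )
        post.append(
            Prescription(
                patient_id=patient.patient_id,
                drug=rec.proposed_drug,
                route=rec.proposed_route or "oral",
                daily_dose=float(dose),
                epoch="post",
            )
        )
        return post

    if rec.action == "consolidate_to_monotherapy":
        post = []
        for p in pre:
            if not kb.profile(p.drug).antipsychotic:
                post.append(as_post(p))
            elif p.drug == rec.proposed_drug:
                post.append(as_post(p))
            elif policy.hypnotic_exemption and _hypnotic_exempt(p, kb):
                post.append(as_post(p))
        return post

    if rec.action == "reduce_dose":
        conflicts = _conflicts_quiet(patient, "pre", kb, policy.use_phenoconversion)
        flagged = {c.drug for c in conflicts if kb.profile(c.drug).antipsychotic}
        post = []
        for p in pre:
            if p.drug in flagged and p.drug in kb.thresholds.thresholds:
                post.append(as_post(p, dose=min(p.daily_dose, kb.thresholds.threshold(p.drug))))
            else:
                post.append(as_post(p))
        return post

    raise ValueError(f"unhandled action {rec.action!r}")


def recommendations_to_frame(recs: list[Recommendation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "action": r.action,
                "proposed_drug": r.proposed_drug or "",
                "proposed_route": r.proposed_route or "",
                "n_triggers": len(r.triggers),
                "triggers": ";".join(r.triggers),
                "rationale": r.rationale,
            }
            for r in recs
        ],
        columns=[
            "patient_id",
            "action",
            "proposed_drug",
            "proposed_route",
            "n_triggers",
            "triggers",
            "rationale",
        ],
    )
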