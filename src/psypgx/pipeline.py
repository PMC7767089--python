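"""End-to-end pipeline: phenotyping -> interactions/conflicts ->
recommendations -> (optional) applied correction -> cohort statistics.

Every run writes a deterministic report bundle (TSV tables + JSON summary)
plus a manifest recording the seed, knowledge-base digest, and input file
digests, so any output file can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortSpec, apply_intervention, generate, generate_records
from .dosing import summaries_to_frame, summarize_patient
from .interactions import (
    aggregate_by_enzyme,
    cohort_conflicts,
    cohort_interactions,
    conflicts_to_frame,
    interactions_to_frame,
    missing_genotype_coverage,
)
from .kb import KnowledgeBase, load_knowledge_base, serialize_knowledge_base
from .phenotyping import effective_phenotype, genotypic_phenotypes
from .recommend import Policy
from .records import records_from_frames
from .stats import cohort_summary


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str | Path
    seed: int = 0
    # input tables; when absent a cohort is simulated
    patients_path: str | Path | None = None
    prescriptions_path: str | Path | None = None
    n_patients: int = 188
    # KB overrides (bundled defaults when None)
    alleles_path: str | Path | None = None
    drugs_path: str | Path | None = None
    equivalence_path: str | Path | None = None
    thresholds_path: str | Path | None = None
    use_phenoconversion: bool = True
    apply_correction: bool = True
    scopes: tuple[str, ...] = ("all_drugs", "antipsychotics_only")

    def validate(self) -> None:
        for name in ("patients_path", "prescriptions_path", "alleles_path",
                     "drugs_path", "equivalence_path", "thresholds_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p}")
        if (self.patients_path is None) != (self.prescriptions_path is None):
            raise ValueError("patients_path and prescriptions_path go together")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _kb_digest(kb: KnowledgeBase) -> str:
    blob = json.dumps(serialize_knowledge_base(kb), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the manifest dict. Raises :class:`PipelineError` naming the
    failing stage on any error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load_kb"
    try:
        kb = load_knowledge_base(
            config.alleles_path, config.drugs_path,
            config.equivalence_path, config.thresholds_path,
        )
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "load_cohort"
    try:
        if config.patients_path:
            patients_df = pd.read_csv(config.patients_path, keep_default_na=False)
            rx_df = pd.read_csv(config.prescriptions_path, keep_default_na=False)
            patients = records_from_frames(patients_df, rx_df)
            simulated = False
        else:
            spec = CohortSpec(seed=config.seed, n_patients=config.n_patients)
            patients_df, rx_df = generate(spec, kb)
            patients = records_from_frames(patients_df, rx_df)
            simulated = True
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "phenotyping"
    try:
        rows = []
        for p in patients:
            for gene, pheno in sorted(genotypic_phenotypes(p, kb).items()):
                eff, events = effective_phenotype(p, gene, "pre", kb)
                rows.append({
                    "patient_id": p.patient_id,
                    "gene": gene,
                    "genotypic": pheno.category,
                    "effective_pre": eff.category,
                    "phenoconversion": ";".join(
                        f"{e.cause}:{e.direction}:{e.from_category}->{e.to_category}"
                        for e in events
                    ),
                })
        phenos_df = pd.DataFrame(
            rows, columns=["patient_id", "gene", "genotypic", "effective_pre",
                           "phenoconversion"],
        )
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "correction"
    try:
        policy = Policy(use_phenoconversion=config.use_phenoconversion)
        if config.apply_correction:
            patients, recs, audit = apply_intervention(patients, kb, policy=policy)
        else:
            from .recommend import recommend, recommendations_to_frame

            recs = [recommend(p, kb, policy=policy) for p in patients]
            audit = recommendations_to_frame(recs)
        from .records import prescriptions_to_frame

        rx_df = prescriptions_to_frame(patients)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "interactions"
    try:
        epochs = sorted(rx_df["epoch"].unique()) if not rx_df.empty else ["pre"]
        interactions = []
        for epoch in epochs:
            for scope in config.scopes:
                interactions.extend(cohort_interactions(patients, kb, epoch, scope))
        conflicts = []
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # missing genotypes summarized below
            for epoch in epochs:
                conflicts.extend(
                    cohort_conflicts(
                        patients, kb, epoch,
                        use_phenoconversion=config.use_phenoconversion,
                    )
                )
        coverage = missing_genotype_coverage(patients, kb)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "dosing"
    try:
        summaries = []
        for p in patients:
            for epoch in epochs:
                rx = p.prescriptions_for(epoch)
                if rx:
                    summaries.append(summarize_patient(rx, kb))
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "statistics"
    try:
        summary = cohort_summary(patients_df, rx_df, kb)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "report"
    try:
        if simulated:
            patients_df.to_csv(out / "patients.csv", index=False, lineterminator="\n")
        rx_df.to_csv(out / "prescriptions.csv", index=False, lineterminator="\n")
        _write_tsv(phenos_df, out / "phenotypes.tsv")
        _write_tsv(interactions_to_frame(interactions), out / "interactions.tsv")
        _write_tsv(
            aggregate_by_enzyme(interactions), out / "interaction_counts.tsv"
        )
        _write_tsv(conflicts_to_frame(conflicts), out / "conflicts.tsv")
        _write_tsv(aggregate_by_enzyme(conflicts), out / "conflict_counts.tsv")
        _write_tsv(coverage, out / "genotype_coverage.tsv")
        _write_tsv(audit, out / "recommendations.tsv")
        _write_tsv(summaries_to_frame(summaries), out / "dose_summary.tsv")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )

        inputs = {}
        for name in ("patients_path", "prescriptions_path", "alleles_path",
                     "drugs_path", "equivalence_path", "thresholds_path"):
            p = getattr(config, name)
            if p is not None:
                inputs[name] = _sha256(Path(p))
        manifest = {
            "psypgx_version": __version__,
            "seed": config.seed,
            "simulated_cohort": simulated,
            "n_patients": len(patients),
            "kb_sha256": _kb_digest(kb),
            "input_sha256": inputs,
            "use_phenoconversion": config.use_phenoconversion,
            "apply_correction": config.apply_correction,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    return manifest
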