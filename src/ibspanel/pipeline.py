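"""Pipeline orchestration, configuration and report generation.

Runs the full analysis in the study's order -- acquire genotypes (simulate
or read) -> common-variant QC -> IBS/MDS ancestry -> additive association
(overall + per subtype) -> rare-variant prioritization (voting matrix and
seqr-style routes, monogenic and oligogenic screens) -> kernel burden tests
-> demographic/report tables -- writing every stage artifact as TSV and
recording every configurable choice in a decision log.

A single seed governs all stochastic stages; per-stage sub-seeds are
derived from it so stages can be rerun in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ancestry_mds, assoc_common, burden_skat, qc_filters, rare_prioritize
from .cohort_io import (
    PANEL_GENES,
    AnnotationRecord,
    GenotypeMatrix,
    SampleRecord,
    VariantRecord,
    cohort_summary,
    read_annotations,
    read_sample_sheet,
    read_vcf,
    write_annotations,
    write_sample_sheet,
    write_vcf,
)
from .synthetic_cohort import (
    SimulationConfig,
    SyntheticCohort,
    simulate_cohort,
    simulate_reference_panel,
)

__all__ = ["PipelineConfig", "PipelineBundle", "run_pipeline", "generate_report",
           "load_config"]


@dataclass
class PipelineConfig:
    """Declarative configuration for the full pipeline.

    Exactly one of ``simulation`` / ``vcf_path`` must be set: the pipeline
    either generates a synthetic cohort or reads a real one.
    """

    seed: int = 0
    simulation: SimulationConfig | None = None
    vcf_path: str | None = None
    sample_sheet_path: str | None = None
    annotations_path: str | None = None
    reference_vcf_path: str | None = None
    reference_labels_path: str | None = None
    qc: qc_filters.QcThresholds = field(default_factory=qc_filters.QcThresholds)
    ancestry_k_use: int = 3
    ancestry_mode: str = "centroid"       # or "nearest"
    n_mds_computed: int = 10
    n_mds_covariates: int = 2
    n_mds_sensitivity: int = 6
    p_report: float = 0.01
    prioritization: rare_prioritize.PrioritizationConfig = field(
        default_factory=rare_prioritize.PrioritizationConfig
    )
    burden_weights_beta: tuple[float, float] = (1.0, 25.0)
    burden_flat_weights: bool = False
    burden_method: str = "liu"
    reference_per_pop: int = 40
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulation is not None) == (self.vcf_path is not None):
            raise ValueError(
                "exactly one of a SimulationConfig or input file paths must be given"
            )


@dataclass
class PipelineBundle:
    """Everything the pipeline produced, keyed by artifact name."""

    config: PipelineConfig
    artifacts: dict[str, pd.DataFrame] = field(default_factory=dict)
    decision_log: list[tuple[str, Any]] = field(default_factory=list)
    samples: list[SampleRecord] = field(default_factory=list)
    variants: list[VariantRecord] = field(default_factory=list)
    genotypes: GenotypeMatrix | None = None
    annotations: list[AnnotationRecord] = field(default_factory=list)
    mds_components: np.ndarray | None = None
    cohort: SyntheticCohort | None = None

    def log(self, option: str, value: Any) -> None:
        self.decision_log.append((option, value))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.artifacts.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
        pd.DataFrame(self.decision_log, columns=["option", "value"]).to_csv(
            outdir / "decision_log.tsv", sep="\t", index=False
        )


def _derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31 (process-independent)."""
    import zlib

    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
               .generate_state(1)[0] % (2 ** 31))


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    qc_raw = raw.pop("qc", None)
    pri_raw = raw.pop("prioritization", None)
    cfg = PipelineConfig(
        simulation=SimulationConfig(**{
            **sim,
            **{k: tuple(tuple(x) for x in sim[k]) for k in
               ("populations", "planted_effects", "planted_monogenic", "planted_digenic")
               if k in sim},
        }) if sim is not None else None,
        qc=qc_filters.QcThresholds(**qc_raw) if qc_raw else qc_filters.QcThresholds(),
        prioritization=(rare_prioritize.PrioritizationConfig(**pri_raw)
                        if pri_raw else rare_prioritize.PrioritizationConfig()),
        **raw,
    )
    return cfg


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_acquire(bundle: PipelineBundle) -> None:
    cfg = bundle.config
    if cfg.simulation is not None:
        sim = dataclasses.replace(cfg.simulation, seed=_derive_seed(cfg.seed, "simulate"))
        cohort = simulate_cohort(sim)
        bundle.cohort = cohort
        bundle.samples = cohort.samples
        bundle.variants = cohort.variants
        bundle.genotypes = cohort.genotypes
        bundle.annotations = cohort.annotations
        bundle.artifacts["ledger"] = cohort.ledger
        bundle.log("input", f"synthetic cohort (seed {sim.seed})")
    else:
        matrix, variants = read_vcf(cfg.vcf_path)
        samples = read_sample_sheet(cfg.sample_sheet_path)
        order = {s.sample_id: s for s in samples}
        bundle.samples = [order[sid] for sid in matrix.sample_ids]
        bundle.variants = variants
        bundle.genotypes = matrix
        bundle.annotations = (
            read_annotations(cfg.annotations_path, matrix.variant_ids)
            if cfg.annotations_path else []
        )
        bundle.log("input", cfg.vcf_path)
    bundle.artifacts["cohort_summary"] = cohort_summary(bundle.samples)


def _stage_qc(bundle: PipelineBundle) -> GenotypeMatrix:
    cfg = bundle.config
    common, log = qc_filters.apply_qc(
        bundle.genotypes, cfg.qc, stage="common", variants=bundle.variants
    )
    bundle.artifacts["qc_log_common"] = log
    bundle.log("qc.thresholds", dataclasses.asdict(cfg.qc))
    bundle.log("qc.common_variants_kept", common.n_variants)
    return common


def _reference_panel(bundle: PipelineBundle, common: GenotypeMatrix):
    cfg = bundle.config
    if bundle.cohort is not None:
        ref, labels = simulate_reference_panel(
            bundle.cohort, n_per_pop=cfg.reference_per_pop,
            seed=_derive_seed(cfg.seed, "reference"),
        )
        return ref.subset(variant_ids=common.variant_ids), labels
    if cfg.reference_vcf_path and cfg.reference_labels_path:
        ref, _ = read_vcf(cfg.reference_vcf_path)
        labels_df = pd.read_csv(cfg.reference_labels_path, sep="\t")
        labels = dict(zip(labels_df["sample_id"], labels_df["superpop"]))
        shared = [v for v in common.variant_ids if v in set(ref.variant_ids)]
        return ref.subset(variant_ids=shared), labels
    return None, None


def _stage_ancestry(bundle: PipelineBundle, common: GenotypeMatrix):
    cfg = bundle.config
    ref, labels = _reference_panel(bundle, common)
    if ref is None:
        bundle.log("ancestry", "skipped (no reference panel)")
        return None
    shared = [v for v in common.variant_ids if v in set(ref.variant_ids)]
    cohort_part = common.subset(variant_ids=shared)
    merged = GenotypeMatrix(
        cohort_part.sample_ids + ref.sample_ids,
        shared,
        np.vstack([cohort_part.dosage, ref.subset(variant_ids=shared).dosage]),
    )
    D = ancestry_mds.ibs_distance_matrix(merged)
    k = min(cfg.n_mds_computed, merged.n_samples - 1)
    comps = ancestry_mds.classical_mds(D, k)
    n_cohort = cohort_part.n_samples
    ref_components = {
        pop: comps[[n_cohort + i for i, sid in enumerate(ref.sample_ids)
                    if labels[sid] == pop]]
        for pop in ancestry_mds.SUPERPOPULATIONS
    }
    results = ancestry_mds.assign_superpopulation(
        comps[:n_cohort], cohort_part.sample_ids, ref_components,
        k_use=cfg.ancestry_k_use, mode=cfg.ancestry_mode,
    )
    try:
        concordance = ancestry_mds.ethnicity_concordance(results, bundle.samples)
    except ValueError:
        concordance = np.nan
    table = ancestry_mds.ancestry_table(results)
    bundle.artifacts["ancestry"] = table
    bundle.log("ancestry.k_use", cfg.ancestry_k_use)
    bundle.log("ancestry.mode", cfg.ancestry_mode)
    bundle.log("ancestry.concordance_pct", round(float(concordance), 2))
    bundle.mds_components = comps[:n_cohort]
    return bundle.mds_components


def _stage_association(bundle: PipelineBundle, common: GenotypeMatrix) -> None:
    cfg = bundle.config
    overall = assoc_common.run_association_scan(
        common, bundle.samples, bundle.mds_components,
        n_mds=cfg.n_mds_covariates, n_mds_sensitivity=cfg.n_mds_sensitivity,
        p_report=cfg.p_report,
    )
    tables = [assoc_common.results_table(overall)]
    for subtype in ("IBS-C", "IBS-D", "IBS-M", "IBS-U"):
        if not any(s.is_case and s.subtype == subtype for s in bundle.samples):
            continue
        tables.append(
            assoc_common.results_table(
                assoc_common.subtype_scan(
                    common, bundle.samples, subtype, bundle.mds_components,
                    n_mds=cfg.n_mds_covariates, p_report=cfg.p_report,
                )
            )
        )
    assoc = pd.concat(tables, ignore_index=True)
    bundle.artifacts["association"] = assoc
    flagged = assoc[(assoc.p < cfg.p_report) & assoc.converged]
    bundle.artifacts["association_flagged"] = flagged
    ps = assoc.loc[(assoc.model == "overall") & assoc.converged, "p"].dropna()
    if len(ps) >= 10:
        bundle.log("association.lambda", round(assoc_common.genomic_inflation(ps), 4))
    bundle.log("association.n_mds_covariates", cfg.n_mds_covariates)
    bundle.log("association.p_report", cfg.p_report)
    count_rows = []
    for vid in flagged.variant_id.unique():
        tab = assoc_common.genotype_count_table(common, bundle.samples, vid)
        tab.insert(0, "variant_id", vid)
        count_rows.append(tab)
    bundle.artifacts["genotype_counts"] = (
        pd.concat(count_rows, ignore_index=True) if count_rows
        else pd.DataFrame(columns=["variant_id", "group", "hom_major", "het",
                                   "hom_minor", "missing"])
    )


def _stage_prioritize(bundle: PipelineBundle) -> tuple[GenotypeMatrix, dict]:
    cfg = bundle.config
    rare_matrix, rare_log = qc_filters.apply_qc(
        bundle.genotypes, cfg.qc, stage="rare", annotations=bundle.annotations
    )
    bundle.artifacts["qc_log_rare"] = rare_log
    annot_by_id = {a.variant_id: a for a in bundle.annotations}
    var_by_id = {v.variant_id: v for v in bundle.variants}
    quals: dict[str, dict[str, rare_prioritize.QualificationResult]] = {}
    for route in ("matrix", "seqr"):
        quals[route] = {
            vid: rare_prioritize.qualify_rare_variant(
                var_by_id[vid], annot_by_id[vid], route, cfg.prioritization
            )
            for vid in rare_matrix.variant_ids if vid in annot_by_id
        }
    score_rows = []
    for vid in rare_matrix.variant_ids:
        if vid not in annot_by_id:
            continue
        sm = rare_prioritize.score_matrix(annot_by_id[vid])
        score_rows.append(
            {
                "variant_id": vid,
                "gene": var_by_id[vid].gene,
                "damage_score": sm.damage_score,
                "damage_votes": sm.damage_votes,
                "damage_available": sm.damage_available,
                "conservation_score": sm.conservation_score,
                "conservation_votes": sm.conservation_votes,
                "conservation_available": sm.conservation_available,
                "is_damaging": sm.is_damaging,
                "is_conserved": sm.is_conserved,
            }
        )
    bundle.artifacts["score_matrix"] = pd.DataFrame(score_rows)

    events_by_table = {}
    for route, table in (("seqr", "monogenic_seqr"), ("matrix", "monogenic_matrix")):
        qualified = [vid for vid, q in quals[route].items() if q.qualified]
        events: list[rare_prioritize.CandidateInheritanceEvent] = []
        for gene in PANEL_GENES:
            events.extend(
                rare_prioritize.detect_monogenic(
                    rare_matrix, bundle.samples, qualified, gene, bundle.variants,
                    cfg.prioritization,
                )
            )
        events_by_table[table] = events
        bundle.artifacts[table] = rare_prioritize.summarize_carriers(
            events, bundle.samples, bundle.annotations, bundle.variants
        )
    qualified_seqr = [vid for vid, q in quals["seqr"].items() if q.qualified]
    oligo = rare_prioritize.detect_oligogenic(
        rare_matrix, bundle.samples, qualified_seqr, bundle.variants,
        config=cfg.prioritization,
    )
    events_by_table["oligogenic"] = oligo
    bundle.artifacts["oligogenic"] = rare_prioritize.summarize_carriers(
        oligo, bundle.samples, bundle.annotations, bundle.variants
    )
    bundle.log("prioritization.routes", "matrix + seqr")
    bundle.log("prioritization.trap_min", cfg.prioritization.trap_min)
    bundle.log(
        "prioritization.cadd_revel_mode",
        "AND" if cfg.prioritization.cadd_revel_conjunctive else "OR",
    )
    bundle.log("prioritization.symptom_map", dict(cfg.prioritization.symptom_map))
    return rare_matrix, events_by_table


def _stage_burden(bundle: PipelineBundle, rare_matrix: GenotypeMatrix) -> None:
    cfg = bundle.config
    cov, names = assoc_common.build_covariates(
        bundle.samples, bundle.mds_components, cfg.n_mds_covariates
    )
    # burden null model cannot take NaN covariates; impute unknown sex to majority
    cov = cov.copy()
    for c in range(cov.shape[1]):
        col = cov[:, c]
        if np.isnan(col).any():
            fill = np.nanmean(col)
            col[np.isnan(col)] = round(fill)
    results = burden_skat.run_burden(
        rare_matrix, bundle.samples, bundle.annotations, bundle.variants,
        covariates=cov,
        weights_beta=cfg.burden_weights_beta,
        flat_weights=cfg.burden_flat_weights,
        method=cfg.burden_method,
        prioritization=cfg.prioritization,
        rng=np.random.default_rng(_derive_seed(cfg.seed, "burden")),
    )
    bundle.artifacts["burden"] = burden_skat.burden_table(results)
    bundle.log("burden.covariates", names)
    bundle.log("burden.weights", "flat" if cfg.burden_flat_weights
               else f"Beta{cfg.burden_weights_beta}")
    bundle.log("burden.p_method", cfg.burden_method)


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Execute all stages in order; identical config + seed -> identical bundle."""
    bundle = PipelineBundle(config=config)
    bundle.log("seed", config.seed)
    stage = "acquire"
    try:
        _stage_acquire(bundle)
        stage = "qc"
        common = _stage_qc(bundle)
        stage = "ancestry"
        _stage_ancestry(bundle, common)
        stage = "association"
        _stage_association(bundle, common)
        stage = "prioritize"
        rare_matrix, _ = _stage_prioritize(bundle)
        stage = "burden"
        _stage_burden(bundle, rare_matrix)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    if config.output_dir:
        bundle.write(config.output_dir)
        if bundle.cohort is not None:
            out = Path(config.output_dir)
            write_vcf(out / "cohort.vcf", bundle.genotypes, bundle.variants)
            write_sample_sheet(out / "samples.tsv", bundle.samples)
            write_annotations(out / "annotations.tsv", bundle.annotations)
        (Path(config.output_dir) / "report.md").write_text(generate_report(bundle))
    return bundle


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

_REPORT_SECTIONS = (
    ("Demographics", "cohort_summary"),
    ("Ancestry assignment", "ancestry"),
    ("Common-variant associations (p < threshold)", "association_flagged"),
    ("Genotype counts for flagged variants", "genotype_counts"),
    ("Deleteriousness score matrix", "score_matrix"),
    ("Monogenic candidates (CADD/REVEL route)", "monogenic_seqr"),
    ("Monogenic candidates (voting-matrix route)", "monogenic_matrix"),
    ("Digenic / oligogenic candidates", "oligogenic"),
    ("Rare-variant burden", "burden"),
)


def generate_report(bundle: PipelineBundle) -> str:
    """Human-readable report mirroring the analysis tables, plus the
    decision log.  Missing stage artifacts are noted, not fatal."""
    lines = ["# IBS carbohydrate-digestion gene panel report", ""]
    for title, key in _REPORT_SECTIONS:
        lines.append(f"## {title}")
        df = bundle.artifacts.get(key)
        if df is None:
            lines.append("_stage skipped: artifact not available_")
        elif df.empty:
            lines.append("_no rows_")
        else:
            lines.append(df.to_string(index=False, max_rows=60))
        lines.append("")
    lines.append("## Decision log")
    for option, value in bundle.decision_log:
        lines.append(f"- {option}: {value}")
    lines.append("")
    return "\n".join(lines)
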