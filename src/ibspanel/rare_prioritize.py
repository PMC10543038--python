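"""Rare-variant prioritization: voting score matrices, qualification
filters, case-exclusive biallelic (monogenic) detection, digenic/oligogenic
screening, and symptom rescaling.

Two qualification routes are provided.  The *matrix* route votes six
damage-prediction assessments (CADD plus five categorical algorithms) and
four conservation scores against fixed thresholds: a variant is "damaging"
with more than three of six damaging votes and "conserved" with at least
two of four conservation votes, and must additionally be rare in gnomAD
(MAF < 0.01).  The *seqr* route keeps non-synonymous or splice variants
with MAF <= 0.05 that look deleterious by CADD >= 10 or REVEL >= 0.3
(missense), or CADD >= 10 or TRaP above a configurable floor for splice
variants where REVEL is undefined.  CADD and REVEL act as alternatives,
not jointly required; a conjunctive mode is available.

Biallelic (potential compound-heterozygous) genotypes are called without
phase: any two qualifying heterozygous variants in one gene, or one
qualifying homozygous-alternate variant, count.  Monogenic candidates are
retained only when no control shows the same biallelic pattern over the
same variant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    MISSING,
    AnnotationRecord,
    GenotypeMatrix,
    SampleRecord,
    VariantRecord,
)

__all__ = [
    "ScoreMatrixResult",
    "CandidateInheritanceEvent",
    "PrioritizationConfig",
    "damage_prediction_score",
    "conservation_prediction_score",
    "classify_deleterious",
    "qualify_rare_variant",
    "detect_monogenic",
    "detect_oligogenic",
    "rescale_symptom",
    "summarize_carriers",
]

#: Categorical calls counted as a damaging vote.
DAMAGING_CALLS = frozenset(
    {"damaging", "possibly damaging", "probably damaging", "disease causing"}
)
CADD_DAMAGE_THRESHOLD = 12.0  # CADD votes damaging iff strictly above

#: Conservation vote thresholds (strict inequality).
CONSERVATION_THRESHOLDS = {"SiPhy": 12.0, "GERP": 4.4, "phyloP": 1.6, "phastCons": 0.5}

DAMAGE_VOTES_REQUIRED = 4       # "higher than three of six"
CONSERVATION_VOTES_REQUIRED = 2  # "at least two out of four"

KNOWN_DEFICIENCY_GENES = frozenset({"SI", "LCT", "TREH", "SLC5A1", "SLC2A5", "ALDOB"})
CANDIDATE_GENES = frozenset({"MGAM", "SLC5A2"})

#: Rome 0-4 rating -> 0-10 Likert-like severity (endpoints fixed).
DEFAULT_SYMPTOM_MAP = {0: 0, 1: 4, 2: 6, 3: 8, 4: 10}

NONSYNONYMOUS = frozenset({"missense", "splice_region"})


@dataclass(frozen=True)
class PrioritizationConfig:
    """Thresholds for the two qualification routes."""

    matrix_maf_max: float = 0.01        # gnomAD rarity, matrix route (strict <)
    seqr_maf_max: float = 0.05          # gnomAD rarity, seqr route (<=)
    cadd_min: float = 10.0
    revel_min: float = 0.3
    trap_min: float = 0.1               # splice variants, seqr route
    cadd_revel_conjunctive: bool = False
    symptom_map: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_SYMPTOM_MAP)
    )

    def __post_init__(self) -> None:
        m = dict(self.symptom_map)
        if set(m) != {0, 1, 2, 3, 4}:
            raise ValueError("symptom map must cover ratings 0..4")
        if m[0] != 0 or m[4] != 10:
            raise ValueError("symptom map endpoints are fixed: 0 -> 0, 4 -> 10")
        if any(m[i] > m[i + 1] for i in range(4)):
            raise ValueError("symptom map must be monotone")


@dataclass
class ScoreMatrixResult:
    """Voting-matrix deleteriousness summary for one variant."""

    variant_id: str
    damage_score: float | None
    damage_votes: int
    damage_available: int
    conservation_score: float | None
    conservation_votes: int
    conservation_available: int
    is_damaging: bool = False
    is_conserved: bool = False


@dataclass
class CandidateInheritanceEvent:
    """A sample plus the qualifying variant set supporting an inheritance call."""

    sample_id: str
    pattern: str                 # monogenic | digenic | oligogenic
    genes: tuple[str, ...]
    variants: tuple[str, ...]
    case_exclusive: bool
    is_control: bool = False
    tier: str = ""               # known | candidate (oligogenic screen)
    symptom_summary: Mapping[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Voting score matrices
# ---------------------------------------------------------------------------

def damage_prediction_score(annotation: AnnotationRecord) -> ScoreMatrixResult:
    """Fraction of available damage-prediction assessments voting damaging.

    Six assessments: CADD (votes iff > 12) and the categorical calls of
    SIFT, PolyPhen2, LRT, FATHMM and PROVEAN (vote iff the call is one of
    "damaging", "possibly damaging", "probably damaging", "disease
    causing").  The denominator counts only available assessments; the
    score is rounded to two decimals for reporting.
    """
    votes = 0
    available = 0
    if annotation.cadd is not None:
        available += 1
        votes += int(annotation.cadd > CADD_DAMAGE_THRESHOLD)
    for call in annotation.damage_calls.values():
        available += 1
        votes += int(call.strip().lower() in DAMAGING_CALLS)
    score = round(votes / available, 2) if available else None
    return ScoreMatrixResult(
        variant_id=annotation.variant_id,
        damage_score=score,
        damage_votes=votes,
        damage_available=available,
        conservation_score=None,
        conservation_votes=0,
        conservation_available=0,
    )


def conservation_prediction_score(annotation: AnnotationRecord) -> ScoreMatrixResult:
    """Fraction of available conservation scores exceeding their thresholds.

    Thresholds (strict >): SiPhy 12, GERP 4.4, phyloP 1.6, phastCons 0.5.
    """
    votes = 0
    available = 0
    for alg, threshold in CONSERVATION_THRESHOLDS.items():
        value = annotation.conservation_scores.get(alg)
        if value is None:
            continue
        available += 1
        votes += int(value > threshold)
    score = round(votes / available, 2) if available else None
    return ScoreMatrixResult(
        variant_id=annotation.variant_id,
        damage_score=None,
        damage_votes=0,
        damage_available=0,
        conservation_score=score,
        conservation_votes=votes,
        conservation_available=available,
    )


def score_matrix(annotation: AnnotationRecord) -> ScoreMatrixResult:
    """Combined damage + conservation voting summary with classifications."""
    dmg = damage_prediction_score(annotation)
    cons = conservation_prediction_score(annotation)
    result = ScoreMatrixResult(
        variant_id=annotation.variant_id,
        damage_score=dmg.damage_score,
        damage_votes=dmg.damage_votes,
        damage_available=dmg.damage_available,
        conservation_score=cons.conservation_score,
        conservation_votes=cons.conservation_votes,
        conservation_available=cons.conservation_available,
    )
    result.is_damaging, result.is_conserved = classify_deleterious(result)
    return result


def classify_deleterious(result: ScoreMatrixResult) -> tuple[bool, bool]:
    """Absolute vote cutoffs: damaging needs >= 4/6 votes, conserved >= 2/4.

    The cutoffs stay absolute under missing assessments (a variant with
    only three available assessments can never reach four damaging votes).
    """
    return (
        result.damage_votes >= DAMAGE_VOTES_REQUIRED,
        result.conservation_votes >= CONSERVATION_VOTES_REQUIRED,
    )


# ---------------------------------------------------------------------------
# Qualification
# ---------------------------------------------------------------------------

@dataclass
class QualificationResult:
    variant_id: str
    qualified: bool
    route: str
    reasons: list[str]

    def __bool__(self) -> bool:
        return self.qualified


def qualify_rare_variant(
    variant: VariantRecord,
    annotation: AnnotationRecord,
    route: str = "seqr",
    config: PrioritizationConfig | None = None,
) -> QualificationResult:
    """Decide whether a variant qualifies for inheritance screening.

    Both routes require a non-synonymous (missense or splice-region)
    consequence.  The matrix route additionally requires gnomAD MAF < 0.01
    and a damaging + conserved voting-matrix classification; the seqr route
    requires MAF <= 0.05 and deleteriousness by CADD/REVEL (missense) or
    CADD/TRaP (splice).  Genotype-level allelic-ratio QC is applied
    separately (see :func:`ibspanel.qc_filters.mask_allelic_ratio`).
    Every failed criterion is recorded in ``reasons``.
    """
    config = config or PrioritizationConfig()
    reasons: list[str] = []
    ok = True

    if variant.consequence not in NONSYNONYMOUS:
        ok = False
        reasons.append(f"consequence {variant.consequence!r} is not non-synonymous/splice")

    maf = annotation.gnomad_maf
    if route == "matrix":
        if maf is not None and maf >= config.matrix_maf_max:
            ok = False
            reasons.append(f"gnomAD MAF {maf} >= {config.matrix_maf_max}")
        sm = score_matrix(annotation)
        if not sm.is_damaging:
            ok = False
            reasons.append(
                f"damage votes {sm.damage_votes}/{sm.damage_available} < "
                f"{DAMAGE_VOTES_REQUIRED}/6"
            )
        if not sm.is_conserved:
            ok = False
            reasons.append(
                f"conservation votes {sm.conservation_votes}/"
                f"{sm.conservation_available} < {CONSERVATION_VOTES_REQUIRED}/4"
            )
    elif route == "seqr":
        if maf is not None and maf > config.seqr_maf_max:
            ok = False
            reasons.append(f"gnomAD MAF {maf} > {config.seqr_maf_max}")
        cadd_ok = annotation.cadd is not None and annotation.cadd >= config.cadd_min
        if variant.consequence == "missense":
            revel_ok = annotation.revel is not None and annotation.revel >= config.revel_min
            passed = (cadd_ok and revel_ok) if config.cadd_revel_conjunctive \
                else (cadd_ok or revel_ok)
            if not passed:
                ok = False
                joiner = "and" if config.cadd_revel_conjunctive else "or"
                reasons.append(
                    f"missense fails CADD >= {config.cadd_min} {joiner} "
                    f"REVEL >= {config.revel_min}"
                )
        else:  # splice / intronic: REVEL undefined, fall back to TRaP
            trap_ok = annotation.trap is not None and annotation.trap >= config.trap_min
            if not (cadd_ok or trap_ok):
                ok = False
                reasons.append(
                    f"splice fails CADD >= {config.cadd_min} or TRaP >= {config.trap_min}"
                )
    else:
        raise ValueError(f"unknown qualification route {route!r}")

    if ok:
        reasons.append("qualified")
    return QualificationResult(variant.variant_id, ok, route, reasons)


# ---------------------------------------------------------------------------
# Inheritance detection
# ---------------------------------------------------------------------------

def _biallelic_variant_set(
    dosages: np.ndarray, variant_ids: Sequence[str]
) -> tuple[str, ...]:
    """Qualifying variants supporting a biallelic call for one sample.

    Returns the supporting set if the sample carries >= 2 heterozygous
    qualifying variants or >= 1 homozygous-alternate qualifying variant in
    the gene; empty tuple otherwise.  Phase is never inferred.
    """
    het = [variant_ids[j] for j in range(len(variant_ids)) if dosages[j] == 1]
    hom = [variant_ids[j] for j in range(len(variant_ids)) if dosages[j] == 2]
    if hom:
        return tuple(sorted(het + hom))
    if len(het) >= 2:
        return tuple(sorted(het))
    return ()


def detect_monogenic(
    matrix: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    qualifying_variants: Sequence[str],
    gene: str,
    variants: Sequence[VariantRecord],
    config: PrioritizationConfig | None = None,
) -> list[CandidateInheritanceEvent]:
    """Case-exclusive biallelic candidates in one gene.

    A case is a candidate iff it carries two or more qualifying
    heterozygous variants in the gene, or at least one qualifying
    homozygous-alternate variant.  The event is suppressed when any control
    satisfies the same biallelic condition within the case's qualifying
    variant set (the study's conservative case-exclusivity rule, applied
    because phase cannot be resolved without parental data).
    """
    config = config or PrioritizationConfig()
    gene_vids = [
        v.variant_id for v in variants
        if v.gene == gene and v.variant_id in set(qualifying_variants)
        and v.variant_id in matrix._variant_index
    ]
    if not gene_vids:
        return []
    sub = matrix.subset(variant_ids=gene_vids)
    status = {s.sample_id: s for s in samples}
    events = []
    control_rows = [i for i, sid in enumerate(sub.sample_ids)
                    if not status[sid].is_case]
    for i, sid in enumerate(sub.sample_ids):
        rec = status[sid]
        if not rec.is_case:
            continue
        support = _biallelic_variant_set(sub.dosage[i], gene_vids)
        if not support:
            continue
        cols = [gene_vids.index(v) for v in support]
        suppressed = any(
            _biallelic_variant_set(sub.dosage[c][cols], list(support))
            for c in control_rows
        )
        if suppressed:
            continue
        events.append(
            CandidateInheritanceEvent(
                sample_id=sid,
                pattern="monogenic",
                genes=(gene,),
                variants=support,
                case_exclusive=True,
                symptom_summary={
                    sym: rescale_symptom(r, config.symptom_map)
                    for sym, r in rec.symptom_ratings.items()
                },
            )
        )
    return events


def detect_oligogenic(
    matrix: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    qualifying_variants: Sequence[str],
    variants: Sequence[VariantRecord],
    known_genes: frozenset[str] = KNOWN_DEFICIENCY_GENES,
    candidate_genes: frozenset[str] = CANDIDATE_GENES,
    config: PrioritizationConfig | None = None,
) -> list[CandidateInheritanceEvent]:
    """Digenic/oligogenic screen: qualifying variants spanning >= 2 genes.

    Events are emitted for controls too (flagged) so case-exclusivity is
    reported rather than silently enforced.  Tier "known" marks events
    whose genes are all established enzyme-deficiency genes; "candidate"
    marks combinations involving the candidate genes.
    """
    config = config or PrioritizationConfig()
    qset = set(qualifying_variants)
    gene_of = {v.variant_id: v.gene for v in variants}
    vids = [v for v in matrix.variant_ids if v in qset and gene_of.get(v)]
    if not vids:
        return []
    sub = matrix.subset(variant_ids=vids)
    events = []
    case_signatures: set[tuple[str, ...]] = set()
    raw = []
    for i, sid in enumerate(sub.sample_ids):
        carried = [vids[j] for j in range(len(vids)) if sub.dosage[i, j] in (1, 2)]
        genes = tuple(sorted({gene_of[v] for v in carried}))
        if len(genes) < 2:
            continue
        raw.append((sid, carried, genes))
    sample_by_id = {s.sample_id: s for s in samples}
    control_gene_sets = {g for sid, _, genes in raw
                         if not sample_by_id[sid].is_case for g in [genes]}
    for sid, carried, genes in raw:
        rec = sample_by_id[sid]
        tier = "known" if set(genes) <= known_genes else "candidate"
        events.append(
            CandidateInheritanceEvent(
                sample_id=sid,
                pattern="digenic" if len(genes) == 2 else "oligogenic",
                genes=genes,
                variants=tuple(sorted(carried)),
                case_exclusive=genes not in control_gene_sets,
                is_control=not rec.is_case,
                tier=tier,
                symptom_summary={
                    sym: rescale_symptom(r, config.symptom_map)
                    for sym, r in rec.symptom_ratings.items()
                },
            )
        )
    return events


# ---------------------------------------------------------------------------
# Symptom rescaling and carrier reporting
# ---------------------------------------------------------------------------

def rescale_symptom(rating: int, mapping: Mapping[int, int] | None = None) -> int:
    """Map a Rome 0-4 severity rating to the 0-10 reporting scale.

    The default table is {0:0, 1:4, 2:6, 3:8, 4:10}; any configured table
    must be monotone with endpoints fixed at 0 -> 0 and 4 -> 10.
    """
    mapping = mapping or DEFAULT_SYMPTOM_MAP
    if rating not in mapping:
        raise ValueError(f"symptom rating {rating!r} outside the 0-4 scale")
    return int(mapping[rating])


def summarize_carriers(
    events: Sequence[CandidateInheritanceEvent],
    samples: Sequence[SampleRecord],
    annotations: Sequence[AnnotationRecord] | None = None,
    variants: Sequence[VariantRecord] | None = None,
    symptom_floor: int = 0,
) -> pd.DataFrame:
    """One report row per event variant: sample, rescaled symptoms, annotations.

    Symptoms at or below ``symptom_floor`` (default 0) are omitted from the
    symptom column, mirroring reports that list only notable symptoms.
    """
    annot_by_id = {a.variant_id: a for a in (annotations or [])}
    var_by_id = {v.variant_id: v for v in (variants or [])}
    rows = []
    for e in events:
        notable = {s: v for s, v in e.symptom_summary.items() if v > symptom_floor}
        symptom_str = "; ".join(
            f"{sym.capitalize()} ({score}/10)" for sym, score in sorted(notable.items())
        )
        for vid in e.variants:
            a = annot_by_id.get(vid)
            v = var_by_id.get(vid)
            rows.append(
                {
                    "sample_id": e.sample_id,
                    "pattern": e.pattern,
                    "tier": e.tier,
                    "case_exclusive": e.case_exclusive,
                    "is_control": e.is_control,
                    "symptoms": symptom_str,
                    "variant_id": vid,
                    "gene": v.gene if v else "",
                    "position": f"{v.chrom}:{v.pos}" if v else "",
                    "hgvs": (v.hgvs or "") if v else "",
                    "trap": a.trap if a else None,
                    "cadd": a.cadd if a else None,
                    "revel": a.revel if a else None,
                    "clinvar": (a.clinvar or "-") if a else "-",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "pattern", "tier", "case_exclusive", "is_control",
                 "symptoms", "variant_id", "gene", "position", "hgvs",
                 "trap", "cadd", "revel", "clinvar"],
    )
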