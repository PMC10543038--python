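"""Variant- and genotype-level quality control.

The common-variant stage applies, in order: multiallelic-origin removal,
the Hardy-Weinberg exact test (p < 1e-6 removed), minor allele frequency
(MAF >= 0.01 kept), call rate (> 0.95 kept), and greedy windowed LD pruning
(r^2 < 0.2, window 50 variants, step 5).  The rare-variant stage masks
individual genotype calls failing the 70:30 allelic-ratio rule and selects
variants rare in gnomAD (MAF < 0.01).  Every removal is logged with the
first failing filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import MISSING, AnnotationRecord, GenotypeMatrix, VariantRecord

__all__ = [
    "QcThresholds",
    "UndefinedLdError",
    "hwe_exact_test",
    "compute_maf",
    "call_rate",
    "ld_r2",
    "ld_prune",
    "allelic_ratio_pass",
    "mask_allelic_ratio",
    "apply_qc",
]


class UndefinedLdError(ValueError):
    """LD is undefined when a dosage vector is constant on the joint support."""


@dataclass(frozen=True)
class QcThresholds:
    """QC thresholds; defaults follow the study's filter cascade."""

    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    ld_r2_max: float = 0.2
    ld_window: int = 50          # window measured in variants
    ld_step: int = 5
    allelic_ratio_min: float = 0.30
    rare_gnomad_maf_max: float = 0.01
    hwe_controls_only: bool = False

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "call_rate_min", "ld_r2_max", "allelic_ratio_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} must be in (0,1]")
        if self.ld_step > self.ld_window:
            raise ValueError("ld_step must be <= ld_window")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of the same parity, the probabilities of configurations no more
    probable than the observed one.  Monomorphic sites return 1.0.  This is
    the standard exact test (not mid-p), symmetric under allele relabeling.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")

    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0

    # P(het = h | allele counts) via the stable mid-out recurrence.
    probs = np.zeros(n_rare + 1)
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs[mid] = 1.0
    het = mid
    hom_r = (n_rare - mid) // 2
    hom_c = n - het - hom_r
    while het > 1:
        probs[het - 2] = probs[het] * het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        het -= 2
        hom_r += 1
        hom_c += 1
    het = mid
    hom_r = (n_rare - mid) // 2
    hom_c = n - het - hom_r
    while het <= n_rare - 2:
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
        hom_r -= 1
        hom_c -= 1
    probs /= probs.sum()
    obs = probs[n_het]
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency over non-missing calls."""
    d = np.asarray(dosages)
    valid = d != MISSING
    if not valid.any():
        raise ValueError("all genotype calls missing; MAF undefined")
    f = d[valid].sum() / (2.0 * valid.sum())
    return float(min(f, 1.0 - f))


def call_rate(dosages: np.ndarray) -> float:
    """Fraction of non-missing genotype calls."""
    d = np.asarray(dosages)
    if d.size == 0:
        raise ValueError("empty dosage vector")
    return float((d != MISSING).sum() / d.size)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared dosage correlation over jointly non-missing samples."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    joint = (np.asarray(dosages_a) != MISSING) & (np.asarray(dosages_b) != MISSING)
    a, b = a[joint], b[joint]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedLdError("a dosage vector is constant on the joint support")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_or_none(a: np.ndarray, b: np.ndarray) -> float | None:
    try:
        return ld_r2(a, b)
    except UndefinedLdError:
        return None


def ld_prune(
    matrix: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    positions: Sequence[int] | None = None,
) -> list[str]:
    """Greedy windowed LD pruning; returns kept variant ids.

    Within each window of ``ld_window`` variants (slid by ``ld_step``),
    while any kept pair has r^2 >= ``ld_r2_max`` the later-positioned
    member is removed.  Passes repeat until a fixpoint, so the result is
    idempotent: no surviving within-window pair violates the threshold.
    Variants are assumed position-sorted (as :func:`read_vcf` guarantees).
    """
    thresholds = thresholds or QcThresholds()
    kept = list(range(matrix.n_variants))
    X = matrix.dosage
    changed = True
    while changed:
        changed = False
        start = 0
        while start < len(kept):
            window = kept[start : start + thresholds.ld_window]
            removed_in_window = True
            while removed_in_window:
                removed_in_window = False
                for ii in range(len(window)):
                    for jj in range(ii + 1, len(window)):
                        r2 = _r2_or_none(X[:, window[ii]], X[:, window[jj]])
                        if r2 is not None and r2 >= thresholds.ld_r2_max:
                            # later-positioned member leaves
                            kept.remove(window[jj])
                            window.pop(jj)
                            removed_in_window = True
                            changed = True
                            break
                    if removed_in_window:
                        break
            start += thresholds.ld_step
    return [matrix.variant_ids[j] for j in kept]


# ---------------------------------------------------------------------------
# Allelic ratio
# ---------------------------------------------------------------------------

def allelic_ratio_pass(
    allele_depth: tuple[int, int],
    dosage: int,
    allelic_ratio_min: float = 0.30,
) -> bool:
    """70:30-style allelic-balance check for a single genotype call.

    Heterozygotes pass iff the alt-read fraction lies in
    [ratio_min, 1 - ratio_min] (boundaries inclusive); homozygous-alt
    requires alt fraction >= 1 - ratio_min; homozygous-ref requires
    alt fraction <= ratio_min.  Zero total depth fails.
    """
    ref_reads, alt_reads = allele_depth
    if ref_reads == MISSING or alt_reads == MISSING:
        return False
    total = ref_reads + alt_reads
    if total <= 0:
        return False
    frac = alt_reads / total
    eps = 1e-9
    if dosage == 1:
        return allelic_ratio_min - eps <= frac <= 1.0 - allelic_ratio_min + eps
    if dosage == 2:
        return frac >= 1.0 - allelic_ratio_min - eps
    if dosage == 0:
        return frac <= allelic_ratio_min + eps
    return False


def mask_allelic_ratio(
    matrix: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, int]:
    """Set genotype calls failing the allelic-ratio rule to missing.

    Returns the masked matrix and the number of masked calls.  Matrices
    without allele depths are returned unchanged.
    """
    thresholds = thresholds or QcThresholds()
    if matrix.allele_depth is None:
        return matrix, 0
    dosage = matrix.dosage.copy()
    n_masked = 0
    for i in range(matrix.n_samples):
        for j in range(matrix.n_variants):
            d = int(dosage[i, j])
            if d == MISSING:
                continue
            depth = (int(matrix.allele_depth[i, j, 0]), int(matrix.allele_depth[i, j, 1]))
            if not allelic_ratio_pass(depth, d, thresholds.allelic_ratio_min):
                dosage[i, j] = MISSING
                n_masked += 1
    return (
        GenotypeMatrix(matrix.sample_ids, matrix.variant_ids, dosage, matrix.allele_depth),
        n_masked,
    )


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def apply_qc(
    matrix: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    stage: str = "common",
    variants: Sequence[VariantRecord] | None = None,
    annotations: Sequence[AnnotationRecord] | None = None,
    control_mask: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the common- or rare-stage QC cascade.

    ``common``: multiallelic removal -> HWE -> MAF -> call rate -> LD prune.
    ``rare``: allelic-ratio genotype masking, then selection of variants
    with gnomAD MAF < ``rare_gnomad_maf_max`` (missing gnomAD frequency
    counts as rare, as for variants absent from the reference database).

    Returns the filtered matrix and a log with one row per removal:
    (variant_id, stage, filter, value, threshold).  Each removed variant is
    logged once, under the first failing filter.
    """
    thresholds = thresholds or QcThresholds()
    log_rows: list[dict] = []

    def log(vid: str, filt: str, value, threshold) -> None:
        log_rows.append(
            {"variant_id": vid, "stage": stage, "filter": filt,
             "value": value, "threshold": threshold}
        )

    if stage == "common":
        by_id = {v.variant_id: v for v in (variants or [])}
        keep: list[str] = []
        for vid in matrix.variant_ids:
            col = matrix.column(vid)
            rec = by_id.get(vid)
            if rec is not None and rec.from_multiallelic:
                log(vid, "multiallelic", 1, 0)
                continue
            valid = col != MISSING
            if not valid.any():
                log(vid, "call_rate", 0.0, thresholds.call_rate_min)
                continue
            hwe_col = col[control_mask] if (thresholds.hwe_controls_only and control_mask is not None) else col
            counts = [int((hwe_col == g).sum()) for g in (0, 1, 2)]
            if sum(counts) > 0:
                p = hwe_exact_test(*counts)
                if p < thresholds.hwe_p_min:
                    log(vid, "hwe", p, thresholds.hwe_p_min)
                    continue
            maf = compute_maf(col)
            if maf < thresholds.maf_min:
                log(vid, "maf", maf, thresholds.maf_min)
                continue
            cr = call_rate(col)
            if cr <= thresholds.call_rate_min:
                log(vid, "call_rate", cr, thresholds.call_rate_min)
                continue
            keep.append(vid)
        pre_ld = matrix.subset(variant_ids=keep)
        kept_after_ld = set(ld_prune(pre_ld, thresholds))
        for vid in keep:
            if vid not in kept_after_ld:
                log(vid, "ld", np.nan, thresholds.ld_r2_max)
        final = [vid for vid in keep if vid in kept_after_ld]
        return matrix.subset(variant_ids=final), pd.DataFrame(
            log_rows, columns=["variant_id", "stage", "filter", "value", "threshold"]
        )

    if stage == "rare":
        masked, _ = mask_allelic_ratio(matrix, thresholds)
        maf_by_id = {a.variant_id: a.gnomad_maf for a in (annotations or [])}
        keep = []
        for vid in masked.variant_ids:
            gmaf = maf_by_id.get(vid)
            if gmaf is not None and gmaf >= thresholds.rare_gnomad_maf_max:
                log(vid, "gnomad_maf", gmaf, thresholds.rare_gnomad_maf_max)
                continue
            keep.append(vid)
        return masked.subset(variant_ids=keep), pd.DataFrame(
            log_rows, columns=["variant_id", "stage", "filter", "value", "threshold"]
        )

    raise ValueError(f"unknown QC stage {stage!r}")
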