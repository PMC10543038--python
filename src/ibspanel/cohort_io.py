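"""Cohort data model and I/O.

The analysis operates on a targeted panel of seven carbohydrate-digestion
genes (*SI*, *MGAM*, *LCT*, *TREH*, *SLC5A1*, *SLC2A5*, *ALDOB*) sequenced
in an IBS case-control cohort.  This module defines the in-memory containers
-- sample phenotype records, biallelic variant records, a samples x variants
dosage matrix with per-call allele depths, and per-variant pathogenicity
annotations -- together with readers and writers for the exchange formats:
multi-sample VCF v4.2 for genotypes and tab-separated tables for sample
sheets, annotations and results.

Conventions: coordinates are 1-based and inclusive as in VCF; multiallelic
VCF records are split into biallelic records at read time and flagged, so
that QC can later drop them; missing genotype metadata is kept as an
explicit category ("unreported"), never silently dropped.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "VariantRecord",
    "GenotypeMatrix",
    "AnnotationRecord",
    "PANEL_GENES",
    "GENE_REGIONS",
    "VcfParseError",
    "EmptyCohortError",
    "read_vcf",
    "write_vcf",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotations",
    "write_annotations",
    "cohort_summary",
]

#: The seven-gene carbohydrate digestion panel.
PANEL_GENES = ("SI", "MGAM", "LCT", "TREH", "SLC5A1", "SLC2A5", "ALDOB")

#: hg19-style target regions per panel gene: (chromosome, start, end).
GENE_REGIONS: dict[str, tuple[str, int, int]] = {
    "SLC2A5": ("1", 9_095_000, 9_110_000),
    "LCT": ("2", 136_545_000, 136_595_000),
    "SI": ("3", 164_696_000, 164_796_000),
    "MGAM": ("7", 141_607_000, 141_806_000),
    "ALDOB": ("9", 104_182_000, 104_198_000),
    "TREH": ("11", 118_528_000, 118_551_000),
    "SLC5A1": ("22", 32_439_000, 32_509_000),
}

STATUSES = ("case", "control")
SUBTYPES = ("IBS-C", "IBS-D", "IBS-M", "IBS-U", "none")
SEXES = ("female", "male", "unknown")
ETHNICITIES = (
    "Native American/Alaska Native",
    "Asian",
    "Black",
    "Hispanic/Latino",
    "Native Hawaiian/Pacific Islander",
    "White",
    "Multiple/Other",
    "unreported",
)
SYMPTOMS = ("pain", "diarrhea", "constipation", "bloating")
CONSEQUENCES = ("missense", "splice_region", "synonymous", "intronic", "UTR", "other")

DAMAGE_ALGORITHMS = ("SIFT", "PolyPhen2", "LRT", "FATHMM", "PROVEAN")
CONSERVATION_ALGORITHMS = ("GERP", "phyloP", "SiPhy", "phastCons")

MISSING = -1  # dosage / depth sentinel


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; the message names the offending line."""


class EmptyCohortError(ValueError):
    """Raised when an operation requires at least one sample."""


@dataclass(frozen=True)
class SampleRecord:
    """Phenotype record for one participant.

    ``symptom_ratings`` holds Rome questionnaire severity ratings on the
    0-4 ordinal scale (absent keys mean missing).
    """

    sample_id: str
    status: str
    subtype: str = "none"
    sex: str = "unknown"
    age: float | None = None
    site: str = ""
    ethnicity: str = "unreported"
    symptom_ratings: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r} for sample {self.sample_id}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r} for sample {self.sample_id}")
        if self.subtype != "none" and self.status != "case":
            raise ValueError(
                f"sample {self.sample_id}: IBS subtype {self.subtype!r} on a control"
            )
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for sample {self.sample_id}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(
                f"unknown ethnicity {self.ethnicity!r} for sample {self.sample_id}"
            )
        for symptom, rating in self.symptom_ratings.items():
            if symptom not in SYMPTOMS:
                raise ValueError(f"unknown symptom {symptom!r}")
            if rating not in (0, 1, 2, 3, 4):
                raise ValueError(
                    f"sample {self.sample_id}: rating {rating!r} for {symptom} "
                    "outside the 0-4 scale"
                )

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant (multiallelic input records are split)."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence: str | None = None
    hgvs: str | None = None
    from_multiallelic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError("VariantRecord must be biallelic (single ALT allele)")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    Dosages are stored as int8 with ``-1`` marking missing calls.  Optional
    per-call allele depths (``ref_reads``, ``alt_reads``) are stored as an
    ``(n_samples, n_variants, 2)`` integer array with ``-1`` for missing.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variant_ids: Sequence[str],
        dosage: np.ndarray,
        allele_depth: np.ndarray | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.variant_ids = list(variant_ids)
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.variant_ids)})"
            )
        bad = ~np.isin(dosage, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        self.dosage = dosage
        if allele_depth is not None:
            allele_depth = np.asarray(allele_depth, dtype=np.int32)
            if allele_depth.shape != dosage.shape + (2,):
                raise ValueError("allele_depth must have shape (n_samples, n_variants, 2)")
        self.allele_depth = allele_depth
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._variant_index = {v: j for j, v in enumerate(self.variant_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def variant_index(self, variant_id: str) -> int:
        return self._variant_index[variant_id]

    def dosage_float(self) -> np.ndarray:
        """Dosage as float64 with missing calls as NaN."""
        out = self.dosage.astype(np.float64)
        out[self.dosage == MISSING] = np.nan
        return out

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_index(variant_id)]

    # -- subsetting ----------------------------------------------------------
    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        variant_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = (
            np.arange(self.n_samples)
            if sample_ids is None
            else np.array([self._sample_index[s] for s in sample_ids], dtype=np.intp)
        )
        cols = (
            np.arange(self.n_variants)
            if variant_ids is None
            else np.array([self._variant_index[v] for v in variant_ids], dtype=np.intp)
        )
        depth = None
        if self.allele_depth is not None:
            depth = self.allele_depth[np.ix_(rows, cols)]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in rows],
            [self.variant_ids[j] for j in cols],
            self.dosage[np.ix_(rows, cols)],
            depth,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same = (
            self.sample_ids == other.sample_ids
            and self.variant_ids == other.variant_ids
            and np.array_equal(self.dosage, other.dosage)
        )
        if not same:
            return False
        if (self.allele_depth is None) != (other.allele_depth is None):
            return False
        if self.allele_depth is not None:
            return np.array_equal(self.allele_depth, other.allele_depth)
        return True


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant deleteriousness / conservation / frequency annotations.

    ``damage_calls`` maps the five categorical damage-prediction algorithms
    (SIFT, PolyPhen2, LRT, FATHMM, PROVEAN) to their call strings;
    ``conservation_scores`` maps GERP, phyloP, SiPhy and phastCons to
    numeric scores.  Absent keys (or None values) mean "not available".
    """

    variant_id: str
    gnomad_maf: float | None = None
    cadd: float | None = None
    revel: float | None = None
    trap: float | None = None
    damage_calls: Mapping[str, str] = field(default_factory=dict)
    conservation_scores: Mapping[str, float] = field(default_factory=dict)
    clinvar: str | None = None

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("gnomad_maf", self.gnomad_maf, 0.0, 1.0),
            ("revel", self.revel, 0.0, 1.0),
            ("trap", self.trap, 0.0, 1.0),
        ):
            if value is not None and not (lo <= value <= hi):
                raise ValueError(
                    f"{name}={value} outside [{lo},{hi}] for variant {self.variant_id}"
                )
        for alg in self.damage_calls:
            if alg not in DAMAGE_ALGORITHMS:
                raise ValueError(f"unknown damage-prediction algorithm {alg!r}")
        for alg in self.conservation_scores:
            if alg not in CONSERVATION_ALGORITHMS:
                raise ValueError(f"unknown conservation algorithm {alg!r}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_CHROM_ORDER = {str(c): i for i, c in enumerate(list(range(1, 23)) + ["X", "Y", "MT"])}


def _chrom_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read a multi-sample VCF into a GenotypeMatrix plus variant records.

    Multiallelic records are split into one biallelic :class:`VariantRecord`
    per ALT allele (flagged ``from_multiallelic``); alleles other than the
    record's own ALT count toward the reference.  Missing genotypes map to
    missing dosage; half-missing calls (``0/.``) are treated as missing.
    The returned variant order is deterministic: (chromosome, position,
    ref, alt).
    """
    import cyvcf2

    path = Path(path)
    with open(path, "rt") as fh:
        first = fh.readline()
    if not first.startswith("##fileformat=VCF"):
        raise VcfParseError(f"{path}: line 1 is not a VCF ##fileformat header")

    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths
        raise VcfParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise EmptyCohortError(f"{path}: VCF contains zero samples")
    n = len(samples)

    records: list[tuple[VariantRecord, np.ndarray, np.ndarray | None]] = []
    for var in vcf:
        alts = var.ALT
        gts = np.array(var.genotype.array()[:, :2], dtype=np.int16)
        ad = None
        if var.FORMAT and "AD" in var.FORMAT:
            ad = np.asarray(var.format("AD"), dtype=np.int32)
        gene = var.INFO.get("GENE")
        for k, alt in enumerate(alts):
            allele = k + 1
            dose = (gts == allele).sum(axis=1).astype(np.int8)
            dose[(gts < 0).any(axis=1)] = MISSING
            depth = None
            if ad is not None and ad.shape[1] > allele:
                depth = np.stack([ad[:, 0], ad[:, allele]], axis=1)
                depth[depth < 0] = MISSING
            vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}:{var.REF}:{alt}"
            if len(alts) > 1:
                vid = f"{var.CHROM}:{var.POS}:{var.REF}:{alt}"
            rec = VariantRecord(
                variant_id=vid,
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alt,
                gene=gene,
                from_multiallelic=len(alts) > 1,
            )
            records.append((rec, dose, depth))
    vcf.close()

    records.sort(key=lambda t: (_chrom_key(t[0].chrom), t[0].pos, t[0].ref, t[0].alt))
    variants = [r for r, _, _ in records]
    m = len(variants)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    have_depth = any(d is not None for _, _, d in records)
    depth_arr = np.full((n, m, 2), MISSING, dtype=np.int32) if have_depth else None
    for j, (_, dose, depth) in enumerate(records):
        dosage[:, j] = dose
        if depth_arr is not None and depth is not None:
            depth_arr[:, j, :] = depth
    return GenotypeMatrix(samples, [v.variant_id for v in variants], dosage, depth_arr), variants


def write_vcf(
    path: str | Path,
    matrix: GenotypeMatrix,
    variants: Sequence[VariantRecord],
) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 with GT (and AD)."""
    if [v.variant_id for v in variants] != matrix.variant_ids:
        raise ValueError("variant records do not match matrix variant order")
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if matrix.allele_depth is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths (ref,alt)">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, v in enumerate(variants):
            info = f"GENE={v.gene}" if v.gene else "."
            fmt = "GT" if matrix.allele_depth is None else "GT:AD"
            cells = []
            for i in range(matrix.n_samples):
                gt = gt_strings[int(matrix.dosage[i, j])]
                if matrix.allele_depth is None:
                    cells.append(gt)
                else:
                    r, a = matrix.allele_depth[i, j]
                    ad = "." if r == MISSING else f"{r},{a}"
                    cells.append(f"{gt}:{ad}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = [
    "sample_id",
    "status",
    "subtype",
    "sex",
    "age",
    "site",
    "ethnicity",
    "pain",
    "diarrhea",
    "constipation",
    "bloating",
]


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a delimited sample sheet (tab or comma) into SampleRecords.

    Unknown vocabulary values and out-of-range symptom ratings raise;
    duplicate sample ids raise.
    """
    path = Path(path)
    with open(path, "rt", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        missing_cols = set(_SHEET_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
        records: list[SampleRecord] = []
        seen: set[str] = set()
        for row in reader:
            sid = row["sample_id"]
            if sid in seen:
                raise ValueError(f"{path}: duplicate sample_id {sid!r}")
            seen.add(sid)
            ratings = {}
            for symptom in SYMPTOMS:
                raw = (row.get(symptom) or "").strip()
                if raw not in ("", "NA", "."):
                    ratings[symptom] = int(raw)
            age_raw = (row.get("age") or "").strip()
            records.append(
                SampleRecord(
                    sample_id=sid,
                    status=row["status"].strip(),
                    subtype=(row.get("subtype") or "none").strip() or "none",
                    sex=(row.get("sex") or "unknown").strip() or "unknown",
                    age=float(age_raw) if age_raw not in ("", "NA", ".") else None,
                    site=(row.get("site") or "").strip(),
                    ethnicity=(row.get("ethnicity") or "unreported").strip() or "unreported",
                    symptom_ratings=ratings,
                )
            )
    return records


def write_sample_sheet(path: str | Path, samples: Iterable[SampleRecord]) -> None:
    with open(path, "wt", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_SHEET_COLUMNS)
        for s in samples:
            writer.writerow(
                [
                    s.sample_id,
                    s.status,
                    s.subtype,
                    s.sex,
                    "" if s.age is None else s.age,
                    s.site,
                    s.ethnicity,
                ]
                + [s.symptom_ratings.get(sym, "") for sym in SYMPTOMS]
            )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = (
    ["variant_id", "gnomad_maf", "cadd", "revel", "trap"]
    + [a.lower() for a in DAMAGE_ALGORITHMS]
    + [a.lower() for a in CONSERVATION_ALGORITHMS]
    + ["clinvar"]
)


def _parse_opt_float(raw: str) -> float | None:
    raw = raw.strip()
    if raw in ("", "NA", "."):
        return None
    return float(raw)


def read_annotations(
    path: str | Path,
    known_variants: Sequence[str] | None = None,
) -> list[AnnotationRecord]:
    """Read the per-variant annotation TSV.

    Missing fields are preserved as missing (never imputed).  If
    ``known_variants`` is given, annotations for unknown variant ids are
    kept but produce a warning.
    """
    path = Path(path)
    known = set(known_variants) if known_variants is not None else None
    records: list[AnnotationRecord] = []
    with open(path, "rt", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            vid = row["variant_id"]
            if known is not None and vid not in known:
                warnings.warn(f"annotation for unknown variant {vid!r} (kept)", stacklevel=2)
            calls = {}
            for alg in DAMAGE_ALGORITHMS:
                raw = (row.get(alg.lower()) or "").strip()
                if raw not in ("", "NA", "."):
                    calls[alg] = raw
            cons = {}
            for alg in CONSERVATION_ALGORITHMS:
                val = _parse_opt_float(row.get(alg.lower()) or "")
                if val is not None:
                    cons[alg] = val
            clinvar = (row.get("clinvar") or "").strip()
            records.append(
                AnnotationRecord(
                    variant_id=vid,
                    gnomad_maf=_parse_opt_float(row.get("gnomad_maf") or ""),
                    cadd=_parse_opt_float(row.get("cadd") or ""),
                    revel=_parse_opt_float(row.get("revel") or ""),
                    trap=_parse_opt_float(row.get("trap") or ""),
                    damage_calls=calls,
                    conservation_scores=cons,
                    clinvar=clinvar if clinvar not in ("", "NA", ".", "-") else None,
                )
            )
    return records


def write_annotations(path: str | Path, annotations: Iterable[AnnotationRecord]) -> None:
    def fmt(v) -> str:
        return "NA" if v is None else str(v)

    with open(path, "wt", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_ANNOT_COLUMNS)
        for a in annotations:
            writer.writerow(
                [a.variant_id, fmt(a.gnomad_maf), fmt(a.cadd), fmt(a.revel), fmt(a.trap)]
                + [a.damage_calls.get(alg, "NA") for alg in DAMAGE_ALGORITHMS]
                + [fmt(a.conservation_scores.get(alg)) for alg in CONSERVATION_ALGORITHMS]
                + [a.clinvar or "NA"]
            )


# ---------------------------------------------------------------------------
# Demographic summary
# ---------------------------------------------------------------------------

def cohort_summary(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Counts and percentages by case/control status for sex, ethnicity, site.

    Returns one row per (category, level) with case / control / overall
    counts and one-decimal percentages; per-category percentages sum to
    100 up to rounding.
    """
    if not samples:
        raise EmptyCohortError("cohort_summary requires a non-empty cohort")
    df = pd.DataFrame(
        {
            "status": [s.status for s in samples],
            "sex": [s.sex for s in samples],
            "ethnicity": [s.ethnicity for s in samples],
            "site": [s.site for s in samples],
            "subtype": [s.subtype for s in samples],
        }
    )
    n_case = int((df.status == "case").sum())
    n_control = int((df.status == "control").sum())
    n_total = len(df)
    rows = []
    for category in ("sex", "ethnicity", "site", "subtype"):
        for level in sorted(df[category].unique()):
            sub = df[df[category] == level]
            c = int((sub.status == "case").sum())
            h = int((sub.status == "control").sum())
            rows.append(
                {
                    "category": category,
                    "level": level,
                    "case_n": c,
                    "case_pct": round(100.0 * c / n_case, 1) if n_case else np.nan,
                    "control_n": h,
                    "control_pct": round(100.0 * h / n_control, 1) if n_control else np.nan,
                    "overall_n": c + h,
                    "overall_pct": round(100.0 * (c + h) / n_total, 1),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_cases"] = n_case
    out.attrs["n_controls"] = n_control
    out.attrs["n_total"] = n_total
    return out
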