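"""Additive-model common-variant association testing.

Each QC-passed variant is tested for association with case/control status
under an additive logistic model (minor-allele dosage 0/1/2) adjusted for
sex and the leading MDS components, reporting the adjusted odds ratio
(aOR), Wald 95% CI and p-value.  Subtype scans compare one IBS subtype's
cases against all controls, excluding cases of the other subtypes.  Also
provided: genotype count tables, an unadjusted allelic odds ratio used as
an oracle companion, and the genomic inflation factor lambda.

The minor allele is defined on the pooled cohort (cases + controls) so the
dosage coding is identical across overall and subtype scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MISSING, GenotypeMatrix, SampleRecord, VariantRecord

__all__ = [
    "AssociationResult",
    "fit_additive_logistic",
    "run_association_scan",
    "subtype_scan",
    "genotype_count_table",
    "allelic_odds_ratio",
    "genomic_inflation",
    "results_table",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class AssociationResult:
    """One variant x model logistic fit."""

    variant_id: str
    model: str
    n_cases: int
    n_controls: int
    beta: float
    se: float
    aor: float
    ci95: tuple[float, float]
    p: float
    covariates: list[str] = field(default_factory=list)
    converged: bool = True
    note: str = ""

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


def _minor_coded(dosage: np.ndarray) -> tuple[np.ndarray, bool]:
    """Recode alt dosage to minor-allele dosage on the pooled cohort."""
    d = np.asarray(dosage, dtype=float)
    d[np.asarray(dosage) == MISSING] = np.nan
    valid = ~np.isnan(d)
    if not valid.any():
        return d, False
    alt_freq = d[valid].sum() / (2 * valid.sum())
    if alt_freq > 0.5:
        return 2.0 - d, True
    return d, False


def fit_additive_logistic(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_id: str = "",
    model: str = "overall",
    covariate_names: Sequence[str] | None = None,
) -> AssociationResult:
    """Additive logistic regression of case status on minor-allele dosage.

    Fits by Newton/IRLS maximum likelihood (tolerance 1e-8, 50 iterations);
    the Wald 95% CI is ``exp(beta +/- 1.96 SE)``.  Complete or
    quasi-complete separation yields a flagged non-converged result rather
    than a spurious estimate.  Samples with missing dosage, phenotype or
    covariates are dropped.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    dose = np.asarray(dosage, dtype=float)
    dose[np.asarray(dosage) == MISSING] = np.nan
    y = np.asarray(phenotype, dtype=float)
    cov = None
    if covariates is not None and np.asarray(covariates).size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
    keep = ~np.isnan(dose) & ~np.isnan(y)
    if cov is not None:
        keep &= ~np.isnan(cov).any(axis=1)
    dose, y = dose[keep], y[keep]
    cov = cov[keep] if cov is not None else None
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    names = list(covariate_names or [])

    def failed(note: str) -> AssociationResult:
        return AssociationResult(
            variant_id, model, n_cases, n_controls, np.nan, np.nan, np.nan,
            (np.nan, np.nan), np.nan, names, converged=False, note=note,
        )

    if n_cases == 0 or n_controls == 0:
        return failed("needs at least one case and one control")
    if np.ptp(dose) == 0:
        return failed("monomorphic")
    X = np.column_stack([np.ones_like(dose), dose] + ([cov] if cov is not None else []))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=50, tol=1e-8, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return failed("separation")
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not (res.mle_retvals.get("converged", False) and np.isfinite(se) and abs(beta) < 20):
        return failed("separation" if abs(beta) >= 20 or not np.isfinite(se) else "non-converged")
    return AssociationResult(
        variant_id=variant_id,
        model=model,
        n_cases=n_cases,
        n_controls=n_controls,
        beta=beta,
        se=se,
        aor=float(np.exp(beta)),
        ci95=(float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))),
        p=float(res.pvalues[1]),
        covariates=names,
        converged=True,
    )


def _phenotype_vector(samples: Sequence[SampleRecord]) -> np.ndarray:
    return np.array([1.0 if s.is_case else 0.0 for s in samples])


def _sex_covariate(samples: Sequence[SampleRecord]) -> np.ndarray:
    """Female = 1, male = 0, unknown sex = NaN (dropped from fits)."""
    code = {"female": 1.0, "male": 0.0, "unknown": np.nan}
    return np.array([code[s.sex] for s in samples])


def build_covariates(
    samples: Sequence[SampleRecord],
    mds_components: np.ndarray | None = None,
    n_mds: int = 2,
) -> tuple[np.ndarray, list[str]]:
    """Sex plus the first ``n_mds`` MDS components, column-stacked."""
    cols = [_sex_covariate(samples)]
    names = ["sex"]
    if mds_components is not None and n_mds > 0:
        comp = np.atleast_2d(np.asarray(mds_components, dtype=float))
        for c in range(min(n_mds, comp.shape[1])):
            cols.append(comp[:, c])
            names.append(f"C{c + 1}")
    return np.column_stack(cols), names


def run_association_scan(
    matrix: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    mds_components: np.ndarray | None = None,
    n_mds: int = 2,
    n_mds_sensitivity: int = 6,
    p_report: float = 0.01,
    model: str = "overall",
) -> list[AssociationResult]:
    """One additive fit per variant, ordered by p-value.

    Variants reaching ``p < p_report`` are flagged and refit with up to
    ``n_mds_sensitivity`` MDS components as a sensitivity analysis; the
    refit is attached to the result's ``note``.
    """
    if [s.sample_id for s in samples] != matrix.sample_ids:
        raise ValueError("sample sheet order must match genotype matrix")
    y = _phenotype_vector(samples)
    cov, names = build_covariates(samples, mds_components, n_mds)
    results = []
    for vid in matrix.variant_ids:
        dose, _ = _minor_coded(matrix.column(vid))
        results.append(
            fit_additive_logistic(dose, y, cov, variant_id=vid, model=model,
                                  covariate_names=names)
        )
    results.sort(key=lambda r: (np.isnan(r.p), r.p))
    if mds_components is not None and n_mds_sensitivity > n_mds:
        cov6, names6 = build_covariates(samples, mds_components, n_mds_sensitivity)
        for r in results:
            if r.converged and r.p < p_report:
                refit = fit_additive_logistic(
                    _minor_coded(matrix.column(r.variant_id))[0], y, cov6,
                    variant_id=r.variant_id, model=r.model, covariate_names=names6,
                )
                r.note = (r.note + f" sensitivity_aOR={refit.aor:.4g} p={refit.p:.4g}").strip()
    return results


def subtype_scan(
    matrix: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    subtype: str,
    mds_components: np.ndarray | None = None,
    n_mds: int = 2,
    p_report: float = 0.01,
) -> list[AssociationResult]:
    """Subtype cases vs all controls, excluding other-subtype cases.

    Minor-allele coding is inherited from the pooled cohort so effect
    directions are comparable with the overall scan.
    """
    if subtype not in ("IBS-C", "IBS-D", "IBS-M", "IBS-U"):
        raise ValueError(f"unknown IBS subtype {subtype!r}")
    keep_idx = [
        i for i, s in enumerate(samples)
        if (s.is_case and s.subtype == subtype) or not s.is_case
    ]
    if not any(samples[i].is_case for i in keep_idx):
        raise ValueError(f"no cases with subtype {subtype}")
    sub_samples = [samples[i] for i in keep_idx]
    y = _phenotype_vector(sub_samples)
    comp = None
    if mds_components is not None:
        comp = np.atleast_2d(np.asarray(mds_components, dtype=float))[keep_idx]
    cov, names = build_covariates(sub_samples, comp, n_mds)
    results = []
    for vid in matrix.variant_ids:
        full_dose, _ = _minor_coded(matrix.column(vid))  # pooled-cohort coding
        dose = full_dose[keep_idx]
        valid = ~np.isnan(dose)
        if valid.sum() == 0 or np.ptp(dose[valid]) == 0:
            results.append(
                AssociationResult(vid, subtype, int(y.sum()), int((1 - y).sum()),
                                  np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan,
                                  names, converged=False, note="monomorphic in subtype+controls")
            )
            continue
        results.append(
            fit_additive_logistic(dose, y, cov, variant_id=vid, model=subtype,
                                  covariate_names=names)
        )
    results.sort(key=lambda r: (np.isnan(r.p), r.p))
    return results


def genotype_count_table(
    matrix: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    variant_id: str,
    grouping: str = "status",
) -> pd.DataFrame:
    """Counts of hom-major / het / hom-minor genotypes per group.

    Genotype classes follow pooled-cohort minor-allele coding; group sums
    equal group sizes net of missing calls.
    """
    if variant_id not in matrix.variant_ids:
        raise KeyError(f"unknown variant {variant_id!r}")
    dose, flipped = _minor_coded(matrix.column(variant_id))
    if grouping == "status":
        groups = [s.status for s in samples]
    elif grouping == "subtype":
        groups = [s.subtype if s.is_case else "control" for s in samples]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for level in sorted(set(groups)):
        mask = np.array([g == level for g in groups])
        d = dose[mask]
        rows.append(
            {
                "group": level,
                "hom_major": int((d == 0).sum()),
                "het": int((d == 1).sum()),
                "hom_minor": int((d == 2).sum()),
                "missing": int(np.isnan(d).sum()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["variant_id"] = variant_id
    out.attrs["minor_is_alt"] = not flipped
    return out


def allelic_odds_ratio(table: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Unadjusted allelic OR from a 2x2 allele-count table with Woolf CI.

    Table layout: rows (case, control), columns (minor, major alleles).
    A 0.5 Haldane-Anscombe correction is applied when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: odds ratio undefined")
    if (t == 0).any():
        t = t + 0.5
    a, b, c, d = t.ravel()
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(odds), (float(odds * np.exp(-_Z95 * se)), float(odds * np.exp(_Z95 * se)))


def genomic_inflation(p_values: Sequence[float]) -> float:
    """Genomic inflation factor: median observed chi2(1) over null median."""
    p = np.asarray([x for x in p_values if np.isfinite(x)], dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def results_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flat results table mirroring the association report layout."""
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "model": [r.model for r in results],
            "n_cases": [r.n_cases for r in results],
            "n_controls": [r.n_controls for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "aOR": [r.aor for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "p": [r.p for r in results],
            "converged": [r.converged for r in results],
            "covariates": [",".join(r.covariates) for r in results],
            "note": [r.note for r in results],
        }
    )
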