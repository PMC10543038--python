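"""Identity-by-state MDS and superpopulation ancestry assignment.

Pairwise genotype sharing is summarized as an identity-by-state (IBS)
distance, embedded with classical (Torgerson) multidimensional scaling,
and each cohort sample is assigned to the nearest of the five continental
reference superpopulations (AFR, AMR, EAS, EUR, SAS) in the space of the
first three components.  Concordance with self-reported ethnicity uses the
study's mapping of ethnicity labels to superpopulations.

The MDS is computed jointly on cohort plus reference individuals (the
reference panel is merged before scaling, not projected afterwards).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import MISSING, GenotypeMatrix, SampleRecord

__all__ = [
    "SUPERPOPULATIONS",
    "ETHNICITY_TO_SUPERPOP",
    "AncestryResult",
    "ibs_distance_matrix",
    "classical_mds",
    "assign_superpopulation",
    "ethnicity_concordance",
]

SUPERPOPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

#: Self-reported ethnicity -> acceptable superpopulations for concordance.
#: "Multiple/Other" and "unreported" are excluded from the denominator.
ETHNICITY_TO_SUPERPOP: dict[str, tuple[str, ...]] = {
    "Native American/Alaska Native": ("EAS",),
    "Asian": ("EAS", "SAS"),
    "Black": ("AFR",),
    "Hispanic/Latino": ("AMR",),
    "Native Hawaiian/Pacific Islander": ("EAS",),
    "White": ("EUR",),
}


@dataclass
class AncestryResult:
    """Per-sample ancestry assignment."""

    sample_id: str
    components: np.ndarray
    assigned_superpop: str
    distances: Mapping[str, float]
    tie: bool = False
    concordant: bool | None = None  # None = not evaluable


def ibs_distance_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise IBS distance: 1 - mean shared-allele fraction.

    The shared-allele fraction at one variant is ``1 - |d_i - d_j| / 2``
    (1 for identical genotypes, 0 for opposite homozygotes), averaged over
    variants where both samples are called.  The result is symmetric with a
    zero diagonal.
    """
    n = matrix.n_samples
    if n < 2:
        raise ValueError("IBS distances need at least two samples")
    X = matrix.dosage_float()
    valid = ~np.isnan(X)
    Xz = np.nan_to_num(X)
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(Xz[i] - Xz)          # |d_i - d_j| where both valid
        joint = valid[i] & valid
        diff = np.where(joint, diff, 0.0)
        counts = joint.sum(axis=1)
        if (counts == 0).any():
            j = int(np.argmin(counts))
            raise ValueError(
                f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
                "share no non-missing variants"
            )
        with np.errstate(invalid="ignore"):
            D[i] = (diff.sum(axis=1) / 2.0) / counts
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def classical_mds(distances: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix to k components.

    Double-centers the squared distances, takes the top-k eigenpairs, and
    scales eigenvectors by the root eigenvalue (negative eigenvalues are
    truncated to zero).  Components are ordered by decreasing eigenvalue
    and the sign of each is fixed so its largest-magnitude loading is
    positive.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    for c in range(k):
        col = coords[:, c]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords


def assign_superpopulation(
    components: np.ndarray,
    sample_ids: Sequence[str],
    reference_components: Mapping[str, np.ndarray],
    k_use: int = 3,
    mode: str = "centroid",
) -> list[AncestryResult]:
    """Assign each sample to the nearest superpopulation.

    Distance from a sample to a superpopulation is the Euclidean distance,
    over the first ``k_use`` MDS components, to the group's centroid
    (``mode="centroid"``, default) or to its nearest member
    (``mode="nearest"``).  Ties are broken lexicographically by label and
    flagged.
    """
    comp = np.atleast_2d(np.asarray(components, dtype=float))[:, :k_use]
    refs: dict[str, np.ndarray] = {}
    for pop in SUPERPOPULATIONS:
        if pop not in reference_components:
            raise ValueError(f"reference panel lacks superpopulation {pop}")
        members = np.atleast_2d(np.asarray(reference_components[pop], dtype=float))
        if members.size == 0:
            raise ValueError(f"reference group {pop} is empty")
        refs[pop] = members[:, :k_use]
    results = []
    for i, sid in enumerate(sample_ids):
        dists: dict[str, float] = {}
        for pop, members in refs.items():
            if mode == "centroid":
                dists[pop] = float(np.linalg.norm(comp[i] - members.mean(axis=0)))
            elif mode == "nearest":
                dists[pop] = float(np.linalg.norm(members - comp[i], axis=1).min())
            else:
                raise ValueError(f"unknown mode {mode!r}")
        best = min(dists.values())
        winners = sorted(pop for pop, d in dists.items() if np.isclose(d, best, rtol=0, atol=1e-12))
        results.append(
            AncestryResult(
                sample_id=sid,
                components=comp[i].copy(),
                assigned_superpop=winners[0],
                distances=dists,
                tie=len(winners) > 1,
            )
        )
    return results


def ethnicity_concordance(
    results: Sequence[AncestryResult],
    samples: Sequence[SampleRecord],
) -> float:
    """Percent of evaluable samples whose assignment matches self-report.

    Uses the ethnicity-to-superpopulation mapping above; "Asian" is
    concordant with either EAS or SAS.  Unreported and Multiple/Other
    samples are excluded from the denominator.  Returns a percentage.
    """
    eth = {s.sample_id: s.ethnicity for s in samples}
    n_eval = 0
    n_conc = 0
    for r in results:
        allowed = ETHNICITY_TO_SUPERPOP.get(eth.get(r.sample_id, "unreported"))
        if allowed is None:
            r.concordant = None
            continue
        n_eval += 1
        r.concordant = r.assigned_superpop in allowed
        n_conc += int(r.concordant)
    if n_eval == 0:
        raise ValueError("no samples evaluable for concordance")
    return 100.0 * n_conc / n_eval


def ancestry_table(results: Sequence[AncestryResult]) -> pd.DataFrame:
    """Flat table of components and assignments, ready for scatter plotting."""
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "assigned_superpop": r.assigned_superpop,
               "tie": r.tie, "concordant": r.concordant}
        for c, val in enumerate(r.components, start=1):
            row[f"C{c}"] = val
        for pop, d in r.distances.items():
            row[f"dist_{pop}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
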