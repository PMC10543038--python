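"""QC filters: HWE exact test against brute-force enumeration, MAF and call
rate, LD r^2 and pruning, the allelic-ratio rule, and the full cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from ibspanel.cohort_io import AnnotationRecord
from ibspanel.qc_filters import (
    QcThresholds,
    UndefinedLdError,
    allelic_ratio_pass,
    apply_qc,
    call_rate,
    compute_maf,
    hwe_exact_test,
    ld_prune,
    ld_r2,
    mask_allelic_ratio,
)
from tests.conftest import make_matrix


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Direct enumeration of the conditional het-count distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare allele copies
    if na == 0:
        return 1.0
    hets = np.arange(na % 2, min(na, 2 * n - na) + 1, 2)
    hom_rare = (na - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1) - gammaln(hom_rare + 1) - gammaln(hets + 1)
        - gammaln(hom_common + 1) + hets * np.log(2)
        + gammaln(na + 1) + gammaln(2 * n - na + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[list(hets).index(n_het)]
    return min(1.0, float(probs[probs <= obs * (1 + 1e-12)].sum()))


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (50, 0, 50), (100, 0, 0), (3, 5, 2), (0, 1, 0), (57, 14, 50)],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), abs=1e-12
    )


def test_hwe_monomorphic_site_is_one():
    assert hwe_exact_test(100, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 7) == 1.0


@given(
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_hwe_allele_relabel_symmetry(a, h, b):
    if a + h + b == 0:
        return
    assert hwe_exact_test(a, h, b) == pytest.approx(hwe_exact_test(b, h, a), abs=1e-14)
    assert 0 < hwe_exact_test(a, h, b) <= 1.0


def test_hwe_rejects_empty_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# MAF / call rate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dosages, expected",
    [([1, 1, 1, 1], 0.5), ([2, 1, 0, 0], 0.375), ([0, 0, 0], 0.0), ([2, 2, 2], 0.0)],
)
def test_compute_maf(dosages, expected):
    assert compute_maf(np.array(dosages)) == pytest.approx(expected)


def test_compute_maf_all_missing_rejected():
    with pytest.raises(ValueError):
        compute_maf(np.array([-1, -1]))


def test_call_rate():
    assert call_rate(np.array([0, 1, 2])) == 1.0
    assert call_rate(np.array([-1] + [0] * 19)) == 0.95
    assert call_rate(np.array([-1, -1])) == 0.0


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_ld_identical_and_anticorrelated_vectors(rng):
    a = rng.integers(0, 3, size=50)
    a[0], a[1] = 0, 2  # guarantee polymorphic
    assert ld_r2(a, a) == pytest.approx(1.0)
    assert ld_r2(a, 2 - a) == pytest.approx(1.0)


def test_ld_matches_direct_correlation_oracle(rng):
    a = rng.integers(0, 3, size=1000).astype(float)
    b = rng.integers(0, 3, size=1000).astype(float)
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    expected = cov ** 2 / (a.var() * b.var())
    assert ld_r2(a, b) == pytest.approx(expected, abs=1e-12)


def test_ld_constant_vector_is_undefined(rng):
    a = rng.integers(0, 3, size=20)
    a[:2] = [0, 2]
    with pytest.raises(UndefinedLdError):
        ld_r2(a, np.ones(20, dtype=int))


def test_ld_uses_jointly_nonmissing_support():
    a = np.array([0, 1, 2, -1, 2, 0])
    b = np.array([0, 1, 2, 2, -1, 0])
    # joint support is indices 0,1,2,5 where a == b
    assert ld_r2(a, b) == pytest.approx(1.0)


def brute_force_greedy_prune(dosage, window, step, r2_max):
    """Reference implementation: same greedy rule, independent code path."""
    def pair_r2(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return None
        return np.corrcoef(x, y)[0, 1] ** 2

    kept = list(range(dosage.shape[1]))
    while True:
        removed_any = False
        start = 0
        while start < len(kept):
            window_idx = kept[start:start + window]
            done = False
            while not done:
                done = True
                for x in range(len(window_idx)):
                    for y in range(x + 1, len(window_idx)):
                        r2 = pair_r2(dosage[:, window_idx[x]], dosage[:, window_idx[y]])
                        if r2 is not None and r2 >= r2_max:
                            kept.remove(window_idx[y])
                            window_idx.pop(y)
                            done = False
                            removed_any = True
                            break
                    if not done:
                        break
            start += step
        if not removed_any:
            return kept


def test_prune_keeps_earlier_of_duplicated_pair(rng):
    col = rng.integers(0, 3, size=40)
    col[:2] = [0, 2]
    dosage = np.column_stack([col, col])
    matrix, _ = make_matrix(dosage)
    kept = ld_prune(matrix)
    assert kept == [matrix.variant_ids[0]]


def test_prune_leaves_uncorrelated_variants(rng):
    dosage = rng.integers(0, 3, size=(500, 8))
    matrix, _ = make_matrix(dosage)
    thresholds = QcThresholds(ld_window=8, ld_step=2)
    pairwise_max = max(
        ld_r2(dosage[:, i], dosage[:, j])
        for i in range(8) for j in range(i + 1, 8)
    )
    assert pairwise_max < 0.2  # premise of the check
    assert ld_prune(matrix, thresholds) == matrix.variant_ids


def test_prune_matches_brute_force_on_correlated_triple(rng):
    base = rng.integers(0, 3, size=200)
    base[:2] = [0, 2]
    noise = rng.integers(0, 3, size=(200, 7))
    dosage = np.column_stack(
        [noise[:, :3], base, base, np.clip(base + (rng.random(200) < 0.05), 0, 2),
         noise[:, 3:]]
    ).astype(np.int8)
    matrix, _ = make_matrix(dosage)
    thresholds = QcThresholds(ld_window=10, ld_step=3)
    kept = ld_prune(matrix, thresholds)
    expected = brute_force_greedy_prune(dosage, 10, 3, 0.2)
    assert kept == [matrix.variant_ids[j] for j in expected]


def test_prune_is_idempotent(rng):
    dosage = rng.integers(0, 3, size=(100, 30))
    dosage[:, 10] = dosage[:, 3]
    dosage[:, 25] = dosage[:, 4]
    matrix, _ = make_matrix(dosage)
    thresholds = QcThresholds(ld_window=6, ld_step=2)
    kept = ld_prune(matrix, thresholds)
    pruned_again = ld_prune(matrix.subset(variant_ids=kept), thresholds)
    assert pruned_again == kept


# ---------------------------------------------------------------------------
# Allelic ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "depth, dosage, expected",
    [
        ((50, 50), 1, True),
        ((80, 20), 1, False),   # 0.20 < 0.30
        ((70, 30), 1, True),    # boundary inclusive
        ((30, 70), 1, True),
        ((2, 98), 2, True),
        ((40, 60), 2, False),
        ((98, 2), 0, True),
        ((60, 40), 0, False),
        ((0, 0), 1, False),     # zero depth fails
    ],
)
def test_allelic_ratio_rule(depth, dosage, expected):
    assert allelic_ratio_pass(depth, dosage) is expected


def test_mask_allelic_ratio_sets_failures_missing():
    dosage = np.array([[1, 1], [1, 2]], dtype=np.int8)
    depth = np.array(
        [[[50, 50], [80, 20]], [[10, 90], [1, 99]]], dtype=np.int32
    )
    matrix, _ = make_matrix(dosage, allele_depth=depth)
    masked, n_masked = mask_allelic_ratio(matrix)
    assert n_masked == 2
    assert list(masked.dosage[0]) == [1, -1]
    assert list(masked.dosage[1]) == [-1, 2]


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def test_cascade_removal_reasons(rng):
    n = 400
    good = rng.binomial(2, 0.3, size=n)
    hwe_bad = np.array([0, 2] * (n // 2))          # no hets at 50% frequency
    rare = np.zeros(n, dtype=int); rare[:4] = 1    # cohort MAF 0.005
    low_call = good.copy(); low_call[: int(n * 0.2)] = -1
    dosage = np.column_stack([good, hwe_bad, rare, low_call]).astype(np.int8)
    matrix, variants = make_matrix(dosage)
    filtered, log = apply_qc(matrix, stage="common", variants=variants)
    assert filtered.variant_ids == [matrix.variant_ids[0]]
    reasons = dict(zip(log.variant_id, log["filter"]))
    assert reasons[matrix.variant_ids[1]] == "hwe"
    assert reasons[matrix.variant_ids[2]] == "maf"
    assert reasons[matrix.variant_ids[3]] == "call_rate"
    # removal reasons partition the removed set: one row per removed variant
    assert sorted(log.variant_id) == sorted(set(log.variant_id))


def test_hwe_threshold_side():
    # 1000 samples, alternating hom classes only: exact p far below 1e-6
    dosage = np.tile([0, 2], 500)[:, None].astype(np.int8)
    matrix, variants = make_matrix(dosage)
    p = hwe_exact_test(500, 0, 500)
    assert p < 1e-6
    _, log = apply_qc(matrix, stage="common", variants=variants)
    assert log.iloc[0]["filter"] == "hwe"


def test_rare_stage_keeps_gnomad_rare_variants():
    dosage = np.array([[1], [0], [0], [0]], dtype=np.int8)
    matrix, variants = make_matrix(dosage)
    vid = matrix.variant_ids[0]
    rare_ann = [AnnotationRecord(vid, gnomad_maf=0.005)]
    common_ann = [AnnotationRecord(vid, gnomad_maf=0.2)]
    kept, _ = apply_qc(matrix, stage="rare", annotations=rare_ann)
    assert kept.variant_ids == [vid]
    dropped, log = apply_qc(matrix, stage="rare", annotations=common_ann)
    assert dropped.variant_ids == []
    assert log.iloc[0]["filter"] == "gnomad_maf"


def test_multiallelic_split_removed_at_common_stage(rng):
    dosage = rng.binomial(2, 0.3, size=(200, 2)).astype(np.int8)
    matrix, variants = make_matrix(dosage)
    variants[1] = type(variants[1])(
        variant_id=variants[1].variant_id, chrom="3", pos=variants[1].pos,
        ref="A", alt="G", gene="SI", consequence="missense", from_multiallelic=True,
    )
    filtered, log = apply_qc(matrix, stage="common", variants=variants)
    assert matrix.variant_ids[1] not in filtered.variant_ids
    assert log.set_index("variant_id").loc[matrix.variant_ids[1], "filter"] == "multiallelic"
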