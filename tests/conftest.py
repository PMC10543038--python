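import numpy as np
import pytest

from ibspanel.cohort_io import GenotypeMatrix, SampleRecord, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_samples(n_cases, n_controls, **kwargs):
    """Minimal sample records: S1..Sn cases first, then controls."""
    out = []
    for i in range(n_cases):
        out.append(SampleRecord(sample_id=f"CASE{i + 1}", status="case", **kwargs))
    for i in range(n_controls):
        out.append(SampleRecord(sample_id=f"CTRL{i + 1}", status="control", **kwargs))
    return out


def make_matrix(dosage, gene="SI", chrom="3", start=164_700_000, sample_ids=None,
                allele_depth=None):
    """GenotypeMatrix + matching VariantRecords from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    variants = [
        VariantRecord(
            variant_id=f"{chrom}:{start + 10 * j}:A:G",
            chrom=chrom, pos=start + 10 * j, ref="A", alt="G",
            gene=gene, consequence="missense",
        )
        for j in range(m)
    ]
    matrix = GenotypeMatrix(sample_ids, [v.variant_id for v in variants], dosage,
                            allele_depth)
    return matrix, variants


@pytest.fixture
def toy_matrix():
    dosage = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
            [0, 0, 0, 0],
            [1, 2, 1, 0],
        ],
        dtype=np.int8,
    )
    return make_matrix(dosage)
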