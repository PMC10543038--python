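"""Voting score matrices, qualification routes, biallelic and oligogenic
detection, symptom rescaling and carrier reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibspanel.cohort_io import AnnotationRecord, SampleRecord
from ibspanel.rare_prioritize import (
    CandidateInheritanceEvent,
    PrioritizationConfig,
    classify_deleterious,
    conservation_prediction_score,
    damage_prediction_score,
    detect_monogenic,
    detect_oligogenic,
    qualify_rare_variant,
    rescale_symptom,
    score_matrix,
    summarize_carriers,
)
from tests.conftest import make_matrix, make_samples

DAMAGING = {"SIFT": "damaging", "PolyPhen2": "probably damaging",
            "LRT": "disease causing", "FATHMM": "damaging", "PROVEAN": "damaging"}
BENIGN = {"SIFT": "tolerated", "PolyPhen2": "benign", "LRT": "neutral",
          "FATHMM": "tolerated", "PROVEAN": "neutral"}


# ---------------------------------------------------------------------------
# Score matrices
# ---------------------------------------------------------------------------

def test_damage_score_five_of_six_is_083():
    ann = AnnotationRecord("v", cadd=8.0, damage_calls=DAMAGING)  # CADD abstains
    res = damage_prediction_score(ann)
    assert (res.damage_votes, res.damage_available) == (5, 6)
    assert res.damage_score == 0.83


def test_damage_score_zero_of_six():
    ann = AnnotationRecord("v", cadd=5.0, damage_calls=BENIGN)
    assert damage_prediction_score(ann).damage_score == 0.0


def test_damage_score_uses_available_denominator():
    # 2 damaging of 3 available -> 0.67 (the varying-denominator rule)
    ann = AnnotationRecord("v", cadd=20.0, damage_calls={"SIFT": "damaging",
                                                         "PolyPhen2": "benign"})
    res = damage_prediction_score(ann)
    assert (res.damage_votes, res.damage_available) == (2, 3)
    assert res.damage_score == 0.67


def test_damage_score_no_assessments_flagged_missing():
    res = damage_prediction_score(AnnotationRecord("v"))
    assert res.damage_score is None and res.damage_available == 0


def test_cadd_votes_strictly_above_12():
    assert damage_prediction_score(AnnotationRecord("v", cadd=12.0)).damage_votes == 0
    assert damage_prediction_score(AnnotationRecord("v", cadd=12.1)).damage_votes == 1


def test_conservation_score_three_of_four_is_075():
    ann = AnnotationRecord("v", conservation_scores={
        "SiPhy": 13.0, "GERP": 4.5, "phyloP": 1.7, "phastCons": 0.4})
    res = conservation_prediction_score(ann)
    assert res.conservation_votes == 3
    assert res.conservation_score == 0.75


def test_conservation_thresholds_are_strict():
    ann = AnnotationRecord("v", conservation_scores={"GERP": 4.4})
    assert conservation_prediction_score(ann).conservation_votes == 0


def test_conservation_all_above_is_one():
    ann = AnnotationRecord("v", conservation_scores={
        "SiPhy": 20.0, "GERP": 5.0, "phyloP": 3.0, "phastCons": 0.9})
    assert conservation_prediction_score(ann).conservation_score == 1.0


@pytest.mark.parametrize(
    "damage_votes, conservation_votes, expected",
    [(4, 0, (True, False)), (3, 0, (False, False)), (0, 2, (False, True)),
     (6, 4, (True, True)), (0, 1, (False, False))],
)
def test_classification_cutoffs(damage_votes, conservation_votes, expected):
    from ibspanel.rare_prioritize import ScoreMatrixResult
    res = ScoreMatrixResult("v", None, damage_votes, 6, None, conservation_votes, 4)
    assert classify_deleterious(res) == expected


@given(
    cadd=st.one_of(st.none(), st.floats(0, 60)),
    n_damaging=st.integers(0, 5),
    n_benign=st.integers(0, 5),
    bump=st.floats(0, 30),
)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_votes_are_threshold_monotone(cadd, n_damaging, n_benign, bump):
    """Raising CADD never removes a vote; adding a non-voting assessment
    never increases the score."""
    algs = ["SIFT", "PolyPhen2", "LRT", "FATHMM", "PROVEAN"]
    calls = {}
    for alg in algs[:n_damaging]:
        calls[alg] = "damaging"
    for alg in algs[n_damaging:min(5, n_damaging + n_benign)]:
        calls[alg] = "tolerated"
    base = damage_prediction_score(AnnotationRecord("v", cadd=cadd, damage_calls=calls))
    if base.damage_available:
        assert 0.0 <= base.damage_score <= 1.0
    if cadd is not None:
        raised = damage_prediction_score(
            AnnotationRecord("v", cadd=cadd + bump, damage_calls=calls))
        assert raised.damage_votes >= base.damage_votes
    # adding an available non-voting assessment cannot increase the score
    free = [a for a in algs if a not in calls]
    if free:
        extra = dict(calls)
        extra[free[0]] = "tolerated"
        widened = damage_prediction_score(
            AnnotationRecord("v", cadd=cadd, damage_calls=extra))
        if base.damage_available:
            assert widened.damage_score <= base.damage_score


# ---------------------------------------------------------------------------
# Qualification
# ---------------------------------------------------------------------------

def _variant(consequence="missense"):
    from ibspanel.cohort_io import VariantRecord
    return VariantRecord("v1", "22", 32_480_567, "C", "A", gene="SLC5A1",
                         consequence=consequence)


def test_seqr_route_accepts_printed_slc5a1_values():
    ann = AnnotationRecord("v1", gnomad_maf=0.001, cadd=24.3, revel=0.596)
    assert qualify_rare_variant(_variant(), ann, "seqr").qualified


def test_synonymous_variant_excluded_with_reason():
    ann = AnnotationRecord("v1", gnomad_maf=0.001, cadd=30.0, revel=0.9)
    res = qualify_rare_variant(_variant("synonymous"), ann, "seqr")
    assert not res.qualified
    assert any("non-synonymous" in r for r in res.reasons)


def test_common_variant_excluded_on_both_routes():
    ann = AnnotationRecord("v1", gnomad_maf=0.08, cadd=30.0, revel=0.9,
                           damage_calls=DAMAGING,
                           conservation_scores={"SiPhy": 15, "GERP": 5,
                                                "phyloP": 2, "phastCons": 0.9})
    assert not qualify_rare_variant(_variant(), ann, "seqr").qualified
    assert not qualify_rare_variant(_variant(), ann, "matrix").qualified


def test_cadd_revel_disjunctive_by_default():
    # REVEL below 0.3 but CADD >= 10, as in several reported digenic rows
    ann = AnnotationRecord("v1", gnomad_maf=0.01, cadd=23.5, revel=0.16)
    assert qualify_rare_variant(_variant(), ann, "seqr").qualified
    strict = PrioritizationConfig(cadd_revel_conjunctive=True)
    assert not qualify_rare_variant(_variant(), ann, "seqr", strict).qualified


def test_splice_variant_uses_trap_fallback():
    ann = AnnotationRecord("v1", gnomad_maf=0.001, cadd=8.1, trap=0.134)
    assert qualify_rare_variant(_variant("splice_region"), ann, "seqr").qualified
    weak = AnnotationRecord("v1", gnomad_maf=0.001, cadd=8.1, trap=0.05)
    assert not qualify_rare_variant(_variant("splice_region"), weak, "seqr").qualified


def test_matrix_route_requires_damaging_and_conserved():
    good = AnnotationRecord("v1", gnomad_maf=0.001, cadd=20.0,
                            damage_calls=DAMAGING,
                            conservation_scores={"SiPhy": 15, "GERP": 5,
                                                 "phyloP": 2, "phastCons": 0.9})
    assert qualify_rare_variant(_variant(), good, "matrix").qualified
    unconserved = AnnotationRecord("v1", gnomad_maf=0.001, cadd=20.0,
                                   damage_calls=DAMAGING,
                                   conservation_scores={"SiPhy": 1.0, "GERP": 0.0,
                                                        "phyloP": 0.0,
                                                        "phastCons": 0.1})
    res = qualify_rare_variant(_variant(), unconserved, "matrix")
    assert not res.qualified and any("conservation" in r for r in res.reasons)


@given(
    maf=st.one_of(st.none(), st.floats(0, 0.5)),
    cadd=st.one_of(st.none(), st.floats(0, 40)),
    revel=st.one_of(st.none(), st.floats(0, 1)),
    consequence=st.sampled_from(["missense", "splice_region", "synonymous"]),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_every_failure_carries_a_reason(maf, cadd, revel, consequence):
    ann = AnnotationRecord("v1", gnomad_maf=maf, cadd=cadd, revel=revel)
    res = qualify_rare_variant(_variant(consequence), ann, "seqr")
    if not res.qualified:
        assert len(res.reasons) >= 1


# ---------------------------------------------------------------------------
# Inheritance detection
# ---------------------------------------------------------------------------

def _cohort(dosage, n_cases, n_controls):
    samples = make_samples(n_cases, n_controls)
    matrix, variants = make_matrix(np.asarray(dosage, dtype=np.int8),
                                   sample_ids=[s.sample_id for s in samples])
    return matrix, variants, samples


def test_two_qualifying_hets_make_a_monogenic_event():
    matrix, variants, samples = _cohort([[1, 1, 0], [0, 0, 0], [0, 0, 0]], 1, 2)
    events = detect_monogenic(matrix, samples, matrix.variant_ids, "SI", variants)
    assert len(events) == 1
    assert events[0].sample_id == "CASE1"
    assert events[0].variants == tuple(sorted(matrix.variant_ids[:2]))


def test_single_het_is_not_biallelic():
    matrix, variants, samples = _cohort([[1, 0, 0], [0, 0, 0]], 1, 1)
    assert detect_monogenic(matrix, samples, matrix.variant_ids, "SI", variants) == []


def test_homozygous_qualifying_variant_counts_as_biallelic():
    matrix, variants, samples = _cohort([[2, 0, 0], [0, 0, 0]], 1, 1)
    events = detect_monogenic(matrix, samples, matrix.variant_ids, "SI", variants)
    assert len(events) == 1 and events[0].variants == (matrix.variant_ids[0],)


def test_control_with_same_pair_suppresses_event():
    matrix, variants, samples = _cohort([[1, 1, 0], [1, 1, 0]], 1, 1)
    assert detect_monogenic(matrix, samples, matrix.variant_ids, "SI", variants) == []


def test_control_suppression_only_removes_events():
    dosage = [[1, 1, 0], [0, 1, 1], [1, 1, 0]]  # case1, case2, control
    matrix, variants, samples = _cohort(dosage, 2, 1)
    with_controls = detect_monogenic(matrix, samples, matrix.variant_ids, "SI",
                                     variants)
    no_controls = detect_monogenic(
        matrix.subset(sample_ids=["CASE1", "CASE2"]), samples[:2],
        matrix.variant_ids, "SI", variants,
    )
    ids_with = {e.sample_id for e in with_controls}
    ids_without = {e.sample_id for e in no_controls}
    assert ids_with <= ids_without
    assert ids_without == {"CASE1", "CASE2"} and ids_with == {"CASE2"}


def test_nonqualifying_variants_ignored():
    matrix, variants, samples = _cohort([[1, 1, 0], [0, 0, 0]], 1, 1)
    events = detect_monogenic(matrix, samples, [matrix.variant_ids[0]], "SI", variants)
    assert events == []


def test_digenic_event_detected_and_tiered():
    from ibspanel.cohort_io import GenotypeMatrix, VariantRecord
    variants = [
        VariantRecord("lct1", "2", 136_562_413, "G", "A", gene="LCT",
                      consequence="missense"),
        VariantRecord("si1", "3", 164_741_534, "T", "C", gene="SI",
                      consequence="missense"),
        VariantRecord("mgam1", "7", 141_794_453, "A", "T", gene="MGAM",
                      consequence="missense"),
    ]
    samples = make_samples(2, 1)
    dosage = np.array([[1, 1, 0],   # case: LCT + SI -> known tier
                       [0, 1, 1],   # case: SI + MGAM -> candidate tier
                       [0, 0, 0]], dtype=np.int8)
    matrix = GenotypeMatrix([s.sample_id for s in samples],
                            [v.variant_id for v in variants], dosage)
    events = detect_oligogenic(matrix, samples, matrix.variant_ids, variants)
    by_sample = {e.sample_id: e for e in events}
    assert by_sample["CASE1"].pattern == "digenic"
    assert by_sample["CASE1"].genes == ("LCT", "SI")
    assert by_sample["CASE1"].tier == "known"
    assert by_sample["CASE2"].tier == "candidate"
    assert "CTRL1" not in by_sample


def test_control_oligogenic_event_flagged_not_hidden():
    matrix, variants, samples = _cohort([[0, 0], [1, 0]], 1, 1)
    from ibspanel.cohort_io import VariantRecord
    variants = [
        VariantRecord(matrix.variant_ids[0], "3", 1, "A", "G", gene="SI",
                      consequence="missense"),
        VariantRecord(matrix.variant_ids[1], "2", 2, "A", "G", gene="LCT",
                      consequence="missense"),
    ]
    dosage = np.array([[0, 0], [1, 1]], dtype=np.int8)
    from ibspanel.cohort_io import GenotypeMatrix
    matrix = GenotypeMatrix([s.sample_id for s in samples],
                            [v.variant_id for v in variants], dosage)
    events = detect_oligogenic(matrix, samples, matrix.variant_ids, variants)
    assert len(events) == 1
    assert events[0].is_control and not events[0].case_exclusive


def test_single_gene_carrier_yields_no_oligogenic_event():
    matrix, variants, samples = _cohort([[1, 1, 0]], 1, 0)
    assert detect_oligogenic(matrix, samples, matrix.variant_ids, variants) == []


# ---------------------------------------------------------------------------
# Symptom rescaling and reporting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rating, expected", [(0, 0), (1, 4), (2, 6), (3, 8), (4, 10)])
def test_default_symptom_rescaling(rating, expected):
    assert rescale_symptom(rating) == expected


def test_symptom_rating_out_of_range_rejected():
    with pytest.raises(ValueError):
        rescale_symptom(5)


def test_symptom_map_endpoints_enforced():
    with pytest.raises(ValueError, match="endpoints"):
        PrioritizationConfig(symptom_map={0: 1, 1: 4, 2: 6, 3: 8, 4: 10})
    with pytest.raises(ValueError, match="monotone"):
        PrioritizationConfig(symptom_map={0: 0, 1: 6, 2: 4, 3: 8, 4: 10})


def test_carrier_report_formats_symptoms():
    samples = [SampleRecord("CASE1", "case",
                            symptom_ratings={"pain": 3, "bloating": 0})]
    event = CandidateInheritanceEvent(
        sample_id="CASE1", pattern="monogenic", genes=("SI",),
        variants=("v1",), case_exclusive=True,
        symptom_summary={"pain": 8, "bloating": 0},
    )
    table = summarize_carriers([event], samples)
    assert table.iloc[0].symptoms == "Pain (8/10)"


def test_carrier_report_empty_symptom_field():
    event = CandidateInheritanceEvent(
        sample_id="CASE1", pattern="monogenic", genes=("SI",),
        variants=("v1",), case_exclusive=True, symptom_summary={"pain": 0},
    )
    table = summarize_carriers([event], [SampleRecord("CASE1", "case")])
    assert table.iloc[0].symptoms == ""
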