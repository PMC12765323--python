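"""Suspicion rules and hypomorph profile envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpbench.classification import ClinicalStatus, PredictedClass
from vpbench.flagger import (
    FlagThresholds,
    build_profile,
    compare_to_profile,
    suspect_misclassification,
)
from vpbench.ingest import AnnotatedVariant, PopulationRecord
from vpbench.reference import hypomorph_population_records, pro1948leu_record
from vpbench.variant_model import make_key


def _variant(predicted, af, hom, cadd, i=1):
    key = make_key("ABCA4", f"A{i}C")
    return AnnotatedVariant(
        key=key,
        score={PredictedClass.BENIGN: 0.1, PredictedClass.AMBIGUOUS: 0.45,
               PredictedClass.PATHOGENIC: 0.9}[predicted],
        predicted_class=predicted,
        clinical_status=ClinicalStatus.ABSENT,
        population=PopulationRecord(key, af, hom, cadd),
    )


def test_rare_damaging_homozygote_free_benign_call_is_suspect_fn():
    # profile of a concordant-pathogenic-like variant predicted benign
    flag = suspect_misclassification(_variant(PredictedClass.BENIGN, 3.79e-5, 0, 24.8))
    assert flag.kind == "SUSPECT_FALSE_NEGATIVE"
    assert len(flag.reasons) == 3  # conjunction: all three rules hold


def test_fn_rule_is_a_conjunction():
    # high CADD + no homozygotes but too common -> no flag
    assert suspect_misclassification(
        _variant(PredictedClass.BENIGN, 5e-3, 0, 30.0)
    ).kind == "NONE"
    # rare + no homozygotes but low CADD -> no flag
    assert suspect_misclassification(
        _variant(PredictedClass.BENIGN, 1e-5, 0, 10.0)
    ).kind == "NONE"


def test_homozygote_presence_alone_trips_fp_rule():
    flag = suspect_misclassification(_variant(PredictedClass.PATHOGENIC, 3.41e-3, 44, 26.2))
    assert flag.kind == "SUSPECT_FALSE_POSITIVE"
    assert any("homozygote" in r for r in flag.reasons)


def test_fp_rule_is_a_disjunction():
    # rare, high CADD, no homozygotes -> concordant-looking pathogenic call
    assert suspect_misclassification(
        _variant(PredictedClass.PATHOGENIC, 1e-6, 0, 28.0)
    ).kind == "NONE"
    # low CADD alone suffices
    assert suspect_misclassification(
        _variant(PredictedClass.PATHOGENIC, 1e-6, 0, 12.0)
    ).kind == "SUSPECT_FALSE_POSITIVE"


def test_common_benign_call_and_ambiguous_never_flagged():
    assert suspect_misclassification(
        _variant(PredictedClass.BENIGN, 0.2, 500, 2.0)
    ).kind == "NONE"
    assert suspect_misclassification(
        _variant(PredictedClass.AMBIGUOUS, 1e-6, 0, 30.0)
    ).kind == "NONE"


def test_threshold_validation():
    with pytest.raises(ValueError):
        FlagThresholds(af_low_max=1e-2, af_high_min=1e-3)
    with pytest.raises(ValueError):
        FlagThresholds(cadd_low_max=25, cadd_high_min=20)


@given(
    af_low=st.floats(1e-7, 1e-4), cadd_high=st.floats(20.0, 30.0),
    tighter_af=st.floats(0.1, 1.0), extra_cadd=st.floats(0.0, 5.0),
)
@settings(max_examples=60, derandomize=True)
def test_tightening_fn_thresholds_never_flags_more(af_low, cadd_high, tighter_af, extra_cadd):
    rng = np.random.default_rng(41)
    cohort = [
        _variant(PredictedClass.BENIGN, 10 ** rng.uniform(-7, -1), int(rng.integers(0, 3)),
                 rng.uniform(5, 35), i + 1)
        for i in range(80)
    ]
    loose = FlagThresholds(af_low_max=af_low, cadd_high_min=cadd_high)
    tight = FlagThresholds(af_low_max=af_low * tighter_af, cadd_high_min=cadd_high + extra_cadd)
    n_loose = sum(suspect_misclassification(v, loose).kind == "SUSPECT_FALSE_NEGATIVE"
                  for v in cohort)
    n_tight = sum(suspect_misclassification(v, tight).kind == "SUSPECT_FALSE_NEGATIVE"
                  for v in cohort)
    assert n_tight <= n_loose


def test_flagging_enriches_for_true_false_negatives():
    """With separated class-conditional metrics, FN recall beats the TN flag rate."""
    rng = np.random.default_rng(7)
    # true FN: pathogenic-like metrics under a benign prediction
    fns = [_variant(PredictedClass.BENIGN, 10 ** rng.normal(-4.7, 0.7), 0,
                    rng.normal(26, 3), i + 1) for i in range(150)]
    # true TN: benign-like metrics
    tns = [_variant(PredictedClass.BENIGN, 10 ** rng.normal(-2.5, 0.8),
                    int(rng.integers(0, 5)), max(0.0, rng.normal(14, 5)), i + 1000)
           for i in range(150)]
    fn_rate = np.mean([suspect_misclassification(v).kind == "SUSPECT_FALSE_NEGATIVE"
                       for v in fns])
    tn_rate = np.mean([suspect_misclassification(v).kind == "SUSPECT_FALSE_NEGATIVE"
                       for v in tns])
    assert fn_rate > tn_rate


def test_profile_medians_of_eight_reference_hypomorphs():
    refs = hypomorph_population_records(exclude="Gly1961Glu")
    assert len(refs) == 8
    profile = build_profile(refs)
    assert profile.allele_frequency.median == pytest.approx(1.355e-3, rel=5e-3)
    assert profile.homozygote_count.median == pytest.approx(5.0)
    assert profile.cadd_phred.median == pytest.approx(25.0)


def test_single_reference_collapses_envelope():
    ref = pro1948leu_record()
    profile = build_profile([ref])
    env = profile.allele_frequency
    assert env.minimum == env.median == env.maximum == ref.allele_frequency


def test_build_profile_empty_errors():
    with pytest.raises(ValueError):
        build_profile([])


@given(st.lists(st.floats(0, 1000), min_size=1, max_size=20))
@settings(max_examples=100, derandomize=True)
def test_profile_median_equals_bruteforce_order_statistics(values):
    refs = [
        PopulationRecord(make_key("G", f"A{i + 1}C"), 1e-3, int(v), v + 1.0)
        for i, v in enumerate(values)
    ]
    profile = build_profile(refs)
    s = sorted(v + 1.0 for v in values)
    n = len(s)
    expected = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
    assert profile.cadd_phred.median == pytest.approx(expected)
    assert profile.cadd_phred.minimum == pytest.approx(s[0])
    assert profile.cadd_phred.maximum == pytest.approx(s[-1])


def test_candidate_hypomorph_falls_within_nine_variant_envelope():
    profile = build_profile(hypomorph_population_records())
    assert profile.n_reference == 9
    cmp = compare_to_profile(pro1948leu_record(), profile)
    assert cmp.overall_within
    assert all(cmp.per_metric.values())


def test_query_outside_envelope_is_reported_per_metric():
    profile = build_profile(hypomorph_population_records())
    query = PopulationRecord(make_key("ABCA4", "A1C"), 1e-3, 5, 50.0)
    cmp = compare_to_profile(query, profile)
    assert not cmp.per_metric["cadd_phred"]
    assert cmp.per_metric["allele_frequency"]
    assert not cmp.overall_within


def test_query_equal_to_reference_is_within():
    refs = hypomorph_population_records()
    profile = build_profile(refs)
    assert compare_to_profile(refs[0], profile).overall_within
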