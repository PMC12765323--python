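"""Welch t-tests, the four group comparisons, and homozygote rates."""

import math

import numpy as np
import pytest

from vpbench.classification import ClinicalStatus, PredictedClass
from vpbench.concordance import ConfusionLabel
from vpbench.discrimination import (
    DiscriminationConfig,
    compare_groups,
    homozygote_rates,
    welch_t,
)
from vpbench.ingest import AnnotatedVariant, PopulationRecord
from vpbench.variant_model import make_key


def welch_oracle(a, b):
    """Textbook-formula re-implementation, independent of the library path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist

    return t, df, 2 * tdist.sf(abs(t), df)


def test_welch_textbook_example_frozen_values():
    t, df, p = welch_t([1, 2, 3, 4], [2, 4, 6, 8, 10])
    assert t == pytest.approx(-2.2514363231593695, abs=1e-12)
    assert df == pytest.approx(5.520787746170677, abs=1e-12)
    assert p == pytest.approx(0.06913359319239237, abs=1e-12)


def test_welch_identical_samples_gives_zero_t_unit_p():
    t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_welch_antisymmetry():
    a, b = [1.0, 3.0, 5.0, 6.0], [2.0, 2.5, 7.0]
    t1, df1, p1 = welch_t(a, b)
    t2, df2, p2 = welch_t(b, a)
    assert t1 == pytest.approx(-t2) and df1 == pytest.approx(df2)
    assert p1 == pytest.approx(p2)


def test_welch_agrees_with_formula_oracle_on_random_inputs():
    rng = np.random.default_rng(17)
    for _ in range(300):
        a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.2, 4), rng.integers(2, 40))
        b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.2, 4), rng.integers(2, 40))
        t, df, p = welch_t(a, b)
        ot, odf, op = welch_oracle(a, b)
        assert t == pytest.approx(ot, abs=1e-10)
        assert df == pytest.approx(odf, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)


def test_welch_error_cases():
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        welch_t([1.0, 1.0], [1.0, 1.0])  # zero variance, equal means
    with pytest.raises(ValueError):
        welch_t([1.0, np.inf], [1.0, 2.0])


def test_bonferroni_threshold_default():
    assert DiscriminationConfig().bonferroni_threshold == pytest.approx(1.25e-2)


def _member(gene, i, predicted, clinical, af, hom, cadd):
    key = make_key(gene, f"A{i}C")
    return AnnotatedVariant(
        key=key,
        score=0.9 if predicted is PredictedClass.PATHOGENIC else 0.1,
        predicted_class=predicted,
        clinical_status=clinical,
        population=PopulationRecord(key, af, hom, cadd),
    )


def _cohort_with_separated_cadd(rng, n=60, delta=8.0):
    """TN vs FN cohort where FN CADD is shifted up by delta."""
    cohort = []
    for i in range(n):
        cohort.append(_member("G1", i + 1, PredictedClass.BENIGN, ClinicalStatus.BENIGN,
                              10 ** rng.uniform(-4, -2), 1, rng.normal(14, 3)))
    for i in range(n):
        cohort.append(_member("G1", i + 1000, PredictedClass.BENIGN, ClinicalStatus.PATHOGENIC,
                              10 ** rng.uniform(-5, -3), 0, rng.normal(14 + delta, 3)))
    # a couple of TP/FP members so those comparisons are computable
    for i in range(3):
        cohort.append(_member("G1", i + 2000, PredictedClass.PATHOGENIC,
                              ClinicalStatus.PATHOGENIC, 1e-5, 0, 26.0))
        cohort.append(_member("G1", i + 3000, PredictedClass.PATHOGENIC,
                              ClinicalStatus.BENIGN, 1e-3, 2, 24.0))
    return cohort


def test_compare_groups_detects_configured_cadd_separation():
    """With an 8-point CADD shift at n=60/group the TN-vs-FN test has near-1 power."""
    rng = np.random.default_rng(23)
    cohort = _cohort_with_separated_cadd(rng)
    comparisons = compare_groups(cohort)
    assert len(comparisons) == 4
    by = {(c.metric, c.group_a, c.group_b): c for c in comparisons}
    cadd_tn_fn = by[("cadd_phred", ConfusionLabel.TN, ConfusionLabel.FN)]
    assert cadd_tn_fn.computable
    assert cadd_tn_fn.significant_after_bonferroni
    assert cadd_tn_fn.mean_b > cadd_tn_fn.mean_a  # FN shifted up


def test_compare_groups_small_group_not_computable():
    rng = np.random.default_rng(3)
    cohort = [
        _member("G1", i, PredictedClass.BENIGN, ClinicalStatus.BENIGN,
                1e-3, 1, rng.normal(14, 3))
        for i in range(1, 11)
    ]
    cohort.append(_member("G1", 99, PredictedClass.PATHOGENIC, ClinicalStatus.BENIGN,
                          1e-3, 0, 25.0))  # exactly one FP
    comparisons = compare_groups(cohort)
    tp_fp = [c for c in comparisons if c.group_b is ConfusionLabel.FP]
    assert len(tp_fp) == 2
    assert all(not c.computable for c in tp_fp)


def test_af_comparison_is_on_log_scale_with_natural_means_reported():
    rng = np.random.default_rng(9)
    cohort = _cohort_with_separated_cadd(rng)
    comparisons = compare_groups(cohort)
    af_tn_fn = next(
        c for c in comparisons
        if c.metric == "log10_allele_frequency" and c.group_a is ConfusionLabel.TN
    )
    assert af_tn_fn.mean_a < 0  # log10 of a frequency < 1
    assert 0 < af_tn_fn.mean_a_natural < 1  # natural-scale mean carried alongside


def test_homozygote_rates_counts_and_order_invariance():
    rng = np.random.default_rng(31)
    cohort = _cohort_with_separated_cadd(rng)
    rows = {r.group: r for r in homozygote_rates(cohort)}
    tn = rows[ConfusionLabel.TN]
    assert tn.n_total == 60 and tn.n_with_homozygote == 60
    assert tn.rate_percent == pytest.approx(100.0)
    fn = rows[ConfusionLabel.FN]
    assert fn.rate_percent == pytest.approx(0.0)

    shuffled = list(cohort)
    rng.shuffle(shuffled)
    rows2 = {r.group: r for r in homozygote_rates(shuffled)}
    assert rows == rows2


def test_homozygote_rate_empty_group_undefined():
    rows = {r.group: r for r in homozygote_rates([])}
    assert all(r.rate_percent is None for r in rows.values())
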