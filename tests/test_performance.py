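"""Wilson intervals, metric formulas, ambiguous policies, panel summaries, ROC/PR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from vpbench.concordance import ConfusionTable
from vpbench.performance import (
    AmbiguousPolicy,
    MacroRule,
    MetricConfig,
    panel_summary,
    performance_metrics,
    roc_pr,
    round_half_up,
    wilson_interval,
)
from vpbench.reference import top20_confusion_tables


def wilson_oracle(k: int, n: int, confidence: float) -> tuple[float, float]:
    """Independent re-implementation from the closed form."""
    z = norm.ppf((1 + confidence) / 2)
    p = k / n
    center = (p + z * z / (2 * n)) / (1 + z * z / n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / (1 + z * z / n)
    return max(0.0, center - half), min(1.0, center + half)


@given(
    n=st.integers(1, 5000),
    frac=st.floats(0, 1),
    confidence=st.sampled_from([0.8, 0.9, 0.95, 0.99]),
)
@settings(max_examples=200, derandomize=True)
def test_wilson_matches_closed_form_and_statsmodels(n, frac, confidence):
    k = round(frac * n)
    lo, hi = wilson_interval(k, n, confidence)
    olo, ohi = wilson_oracle(k, n, confidence)
    assert lo == pytest.approx(olo, abs=1e-12)
    assert hi == pytest.approx(ohi, abs=1e-12)
    slo, shi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    assert lo == pytest.approx(float(slo), abs=1e-9)
    assert hi == pytest.approx(float(shi), abs=1e-9)
    assert 0.0 <= lo <= k / n <= hi <= 1.0


@given(n=st.integers(1, 60), mult=st.integers(2, 50))
@settings(max_examples=100, derandomize=True)
def test_wilson_shrinks_with_n_at_fixed_proportion(n, mult):
    k = n // 2
    lo1, hi1 = wilson_interval(k, n)
    lo2, hi2 = wilson_interval(k * mult, n * mult)
    assert (hi2 - lo2) <= (hi1 - lo1) + 1e-12


def test_wilson_undefined_for_zero_trials():
    with pytest.raises(ValueError):
        wilson_interval(0, 0)
    with pytest.raises(ValueError):
        wilson_interval(3, 2)


def test_metrics_formulas_small_table():
    t = ConfusionTable("x", tp=5, fn=0, tn=5, fp=0)
    for policy in AmbiguousPolicy:
        r = performance_metrics(t, MetricConfig(ambiguous_policy=policy))
        assert r.sensitivity.value == 1.0
        assert r.specificity.value == 1.0
        assert r.fdr.value == 0.0


def test_metrics_undefined_denominators_are_explicit():
    t = ConfusionTable("PRPF31", tp=1, fn=0, tn=0, fp=0)
    r = performance_metrics(t)
    assert r.specificity is None
    assert any("specificity" in reason for reason in r.undefined_reasons)
    assert r.sensitivity.value == 1.0


@given(
    tp=st.integers(0, 500), fn=st.integers(0, 500),
    tn=st.integers(0, 500), fp=st.integers(0, 500),
    ambig_p=st.integers(1, 200), ambig_b=st.integers(1, 200),
)
@settings(max_examples=100, derandomize=True)
def test_exclude_policy_dominates_as_error(tp, fn, tn, fp, ambig_p, ambig_b):
    """Counting ambiguous calls as errors can only hurt each metric."""
    t = ConfusionTable("x", tp=tp, fn=fn, tn=tn, fp=fp, ambig_p=ambig_p, ambig_b=ambig_b)
    excl = performance_metrics(t, MetricConfig(ambiguous_policy=AmbiguousPolicy.EXCLUDE))
    err = performance_metrics(t, MetricConfig(ambiguous_policy=AmbiguousPolicy.AS_ERROR))
    if excl.sensitivity is not None and tp > 0:
        assert excl.sensitivity.value > err.sensitivity.value
    if excl.specificity is not None and tn > 0:
        assert excl.specificity.value > err.specificity.value
    if excl.fdr is not None:
        assert err.fdr.value >= excl.fdr.value


def test_panel_summary_single_gene_is_identity():
    t = ConfusionTable("RHO", tp=29, fn=4, tn=5, fp=1)
    r = performance_metrics(t)
    s = panel_summary([r])
    assert s.macro_sensitivity == pytest.approx(29 / 33)
    assert s.macro_specificity == pytest.approx(5 / 6)
    assert s.micro_fdr == pytest.approx(1 / 30)


def test_panel_summary_published_top20_counts():
    reports = [performance_metrics(t) for t in top20_confusion_tables()]
    s = panel_summary(reports)
    # pooled FDR: 19 false positives among 773 predicted-pathogenic calls
    assert s.micro_fdr == pytest.approx(19 / 773)
    assert round_half_up(100 * s.micro_fdr) == 2.5
    # macro specificity over the 19 genes with tn + fp > 0
    assert s.genes_in_macro_specificity == 19
    assert round_half_up(100 * s.macro_specificity) == 93.3
    # macro sensitivity under both conventions
    assert s.genes_in_macro_sensitivity == 20
    assert round_half_up(100 * s.macro_sensitivity) == 79.1
    s_drop = panel_summary(reports, MacroRule.DROP_ZERO_TP)
    assert s_drop.genes_in_macro_sensitivity == 19
    assert round_half_up(100 * s_drop.macro_sensitivity) == 83.2


def auroc_bruteforce(scores, labels):
    """Pair-counting oracle: P(score_path > score_benign) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == "pathogenic"]
    neg = [s for s, l in zip(scores, labels) if l == "benign"]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_perfect_separation():
    scores = [0.1, 0.2, 0.8, 0.9]
    labels = ["benign", "benign", "pathogenic", "pathogenic"]
    auroc, auprc = roc_pr(scores, labels)
    assert auroc == 1.0 and auprc == 1.0


def test_roc_single_class_errors():
    with pytest.raises(ValueError):
        roc_pr([0.1, 0.9], ["benign", "benign"])


def test_roc_null_property():
    rng = np.random.default_rng(5)
    scores = rng.random(4000)
    labels = np.where(rng.random(4000) < 0.5, "pathogenic", "benign")
    auroc, _ = roc_pr(scores, labels)
    assert auroc == pytest.approx(0.5, abs=0.03)


@given(data=st.data(), n=st.integers(6, 200))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_auroc_equals_pair_counting(data, n):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    # 3-decimal score granularity forces ties, exercising the midrank correction
    scores = np.round(rng.random(n), 3)
    labels = ["pathogenic" if x < 0.4 else "benign" for x in rng.random(n)]
    if len(set(labels)) < 2:
        return
    auroc, _ = roc_pr(scores, labels)
    assert auroc == pytest.approx(auroc_bruteforce(scores, labels), abs=1e-12)


def test_six_point_toy_set_with_one_inversion():
    scores = [0.9, 0.8, 0.55, 0.6, 0.2, 0.1]
    labels = ["pathogenic", "pathogenic", "pathogenic", "benign", "benign", "benign"]
    auroc, _ = roc_pr(scores, labels)
    assert auroc == pytest.approx(auroc_bruteforce(scores, labels), abs=1e-12)
    assert auroc == pytest.approx(8 / 9)
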