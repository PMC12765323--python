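"""Concordance metrics with Wilson confidence intervals.

Sensitivity, specificity, and false discovery rate (FDR = FP / (FP + TP))
are computed from a confusion table under one of two policies for
score-range-ambiguous predictions: exclude them from the denominators
(primary analysis) or count them as errors (sensitivity analysis). Each
defined proportion carries a Wilson score interval — the binomial interval
family whose closed form is

    center = (p + z^2/2n) / (1 + z^2/n),
    half-width = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n),

clamped to [0, 1]. A zero denominator leaves the metric undefined (with the
reason recorded) rather than raising or emitting NaN.

Panel-level summaries pool FP/TP across genes for a micro FDR and average
defined per-gene values for macro sensitivity/specificity. Because a gene
with pathogenic-labelled variants but zero true positives has a defined (0%)
sensitivity, two macro conventions exist; both are implemented and the choice
is explicit (:class:`MacroRule`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import average_precision_score, roc_auc_score

from .classification import ClinicalStatus, CollapsedLabel
from .concordance import ConfusionTable


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (report convention), e.g. 0.25 -> 0.3 at 1 digit."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class AmbiguousPolicy(Enum):
    EXCLUDE = "exclude"
    AS_ERROR = "as_error"


class MacroRule(Enum):
    """Which genes enter a macro average."""

    DEFINED_ONLY = "defined_only"  # any gene whose denominator is > 0
    DROP_ZERO_TP = "drop_zero_tp"  # additionally drop tp == 0 genes from macro sensitivity


@dataclass(frozen=True)
class MetricConfig:
    confidence: float = 0.95
    ambiguous_policy: AmbiguousPolicy = AmbiguousPolicy.EXCLUDE

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence < 1.0):
            raise ValueError(f"confidence must lie in (0, 1), got {self.confidence}")

    @property
    def z(self) -> float:
        return float(norm.ppf(0.5 * (1.0 + self.confidence)))


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for ``k`` successes in ``n`` trials.

    Raises ``ValueError`` when ``n == 0`` (the interval is undefined) or when
    ``k`` is outside ``0..n``.
    """
    if n < 1:
        raise ValueError("Wilson interval undefined for n = 0")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    z = float(norm.ppf(0.5 * (1.0 + confidence)))
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2.0 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # the bounds are exactly 0 (k=0) and 1 (k=n); avoid float residue there
    lower = 0.0 if k == 0 else max(0.0, center - half)
    upper = 1.0 if k == n else min(1.0, center + half)
    return lower, upper


@dataclass(frozen=True)
class Proportion:
    """A binomial proportion k/n with its Wilson interval."""

    k: int
    n: int
    value: float
    lower: float
    upper: float

    @classmethod
    def from_counts(cls, k: int, n: int, confidence: float) -> "Proportion":
        lo, hi = wilson_interval(k, n, confidence)
        return cls(k=k, n=n, value=k / n, lower=lo, upper=hi)

    def percent(self, ndigits: int = 1) -> float:
        return round_half_up(100.0 * self.value, ndigits)


@dataclass(frozen=True)
class PerformanceReport:
    """Sensitivity/specificity/FDR for one scope under one ambiguous policy.

    Metrics with a zero denominator are ``None`` with the reason in
    ``undefined_reasons``.
    """

    scope: str
    policy: AmbiguousPolicy
    sensitivity: Proportion | None
    specificity: Proportion | None
    fdr: Proportion | None
    undefined_reasons: tuple[str, ...] = ()


def performance_metrics(
    table: ConfusionTable, cfg: MetricConfig | None = None
) -> PerformanceReport:
    """Compute sensitivity, specificity, and FDR from a confusion table.

    Under ``AS_ERROR`` the ambiguous buckets are folded into the error cells
    (ambiguous-on-pathogenic into FN, ambiguous-on-benign into FP) before the
    same formulas apply.
    """
    cfg = cfg or MetricConfig()
    tp, tn = table.tp, table.tn
    fn, fp = table.fn, table.fp
    if cfg.ambiguous_policy is AmbiguousPolicy.AS_ERROR:
        fn += table.ambig_p
        fp += table.ambig_b

    reasons: list[str] = []

    def prop(k: int, n: int, name: str) -> Proportion | None:
        if n == 0:
            reasons.append(f"{name} undefined: zero denominator")
            return None
        return Proportion.from_counts(k, n, cfg.confidence)

    report = PerformanceReport(
        scope=table.scope,
        policy=cfg.ambiguous_policy,
        sensitivity=prop(tp, tp + fn, "sensitivity"),
        specificity=prop(tn, tn + fp, "specificity"),
        fdr=prop(fp, fp + tp, "fdr"),
        undefined_reasons=tuple(reasons),
    )
    return report


@dataclass(frozen=True)
class PanelSummary:
    """Macro averages and pooled (micro) FDR across per-gene reports."""

    macro_sensitivity: float | None
    macro_specificity: float | None
    micro_fdr: float | None
    genes_in_macro_sensitivity: int
    genes_in_macro_specificity: int
    genes_in_micro_fdr: int


def panel_summary(
    gene_reports: Sequence[PerformanceReport],
    macro_rule: MacroRule = MacroRule.DEFINED_ONLY,
) -> PanelSummary:
    """Summarize per-gene reports into macro averages and a pooled FDR."""
    if not gene_reports:
        raise ValueError("panel summary requires at least one gene report")

    sens = [r.sensitivity for r in gene_reports if r.sensitivity is not None]
    if macro_rule is MacroRule.DROP_ZERO_TP:
        sens = [p for p in sens if p.k > 0]
    spec = [p for r in gene_reports if (p := r.specificity) is not None]

    fdr_props = [r.fdr for r in gene_reports if r.fdr is not None]
    pooled_fp = sum(p.k for p in fdr_props)
    pooled_n = sum(p.n for p in fdr_props)

    return PanelSummary(
        macro_sensitivity=float(np.mean([p.value for p in sens])) if sens else None,
        macro_specificity=float(np.mean([p.value for p in spec])) if spec else None,
        micro_fdr=pooled_fp / pooled_n if pooled_n else None,
        genes_in_macro_sensitivity=len(sens),
        genes_in_macro_specificity=len(spec),
        genes_in_micro_fdr=len(fdr_props),
    )


def roc_pr(
    scores: Sequence[float],
    labels: Sequence[CollapsedLabel | ClinicalStatus | str],
) -> tuple[float, float]:
    """AUROC and AUPRC of the continuous score, pathogenic as the positive class.

    AUROC uses the rank statistic with midrank tie correction (equivalent to
    the trapezoidal ROC area); AUPRC is the step-wise precision-recall
    summation (average precision). Requires both classes present.
    """
    y = []
    for lab in labels:
        value = lab.value if isinstance(lab, (CollapsedLabel, ClinicalStatus)) else str(lab)
        if value == "pathogenic":
            y.append(1)
        elif value == "benign":
            y.append(0)
        else:
            raise ValueError(
                f"roc_pr accepts only definitive pathogenic/benign labels, got {value!r}"
            )
    if len(y) != len(scores):
        raise ValueError("scores and labels must have equal length")
    if len(set(y)) < 2:
        raise ValueError("roc_pr requires at least one pathogenic and one benign label")
    scores_arr = np.asarray(scores, dtype=float)
    y_arr = np.asarray(y)
    return float(roc_auc_score(y_arr, scores_arr)), float(
        average_precision_score(y_arr, scores_arr)
    )


def reports_to_frame(
    reports: Sequence[PerformanceReport], tables: Sequence[ConfusionTable]
) -> pd.DataFrame:
    """Per-gene report table (counts, point estimates, CI bounds, notes)."""
    by_scope = {t.scope: t for t in tables}
    rows = []
    for r in reports:
        t = by_scope.get(r.scope)
        rows.append(
            {
                "scope": r.scope,
                "policy": r.policy.value,
                "tp": t.tp if t else "",
                "fn": t.fn if t else "",
                "tn": t.tn if t else "",
                "fp": t.fp if t else "",
                "ambig_p": t.ambig_p if t else "",
                "ambig_b": t.ambig_b if t else "",
                "sensitivity": r.sensitivity.value if r.sensitivity else "",
                "sens_lower": r.sensitivity.lower if r.sensitivity else "",
                "sens_upper": r.sensitivity.upper if r.sensitivity else "",
                "specificity": r.specificity.value if r.specificity else "",
                "spec_lower": r.specificity.lower if r.specificity else "",
                "spec_upper": r.specificity.upper if r.specificity else "",
                "fdr": r.fdr.value if r.fdr else "",
                "fdr_lower": r.fdr.lower if r.fdr else "",
                "fdr_upper": r.fdr.upper if r.fdr else "",
                "notes": "; ".join(r.undefined_reasons),
            }
        )
    return pd.DataFrame(rows)
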