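"""Population-metric contrasts between concordant and discordant variants.

Do misclassified predictions look different in the population? Four Welch
t-tests (unequal variances) compare log10 allele frequency and CADD phred
between true positives and false positives, and between true negatives and
false negatives, with Bonferroni correction across the four comparisons
(alpha 0.05 / 4 = 1.25e-2 at defaults). Allele frequency is tested on the
log10 scale — cohort membership requires population presence, so AF > 0 and
no pseudo-count is needed; CADD is already phred-scaled and compared as is.
Homozygote rates (share of variants with at least one reported homozygote)
are tabulated per confusion group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import ConfusionLabel, assign_confusion
from .ingest import AnnotatedVariant


@dataclass(frozen=True)
class DiscriminationConfig:
    alpha: float = 0.05
    n_comparisons: int = 4
    log_base: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")
        if self.log_base != 10:
            raise ValueError("only base-10 log transform is supported")

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_comparisons


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, two-sided p).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with sample variances;
    degrees of freedom by Welch–Satterthwaite (not rounded). Both groups need
    at least two finite values; two zero-variance groups with equal means
    leave t undefined and raise.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.size < 2 or b_arr.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    if not (np.isfinite(a_arr).all() and np.isfinite(b_arr).all()):
        raise ValueError("welch_t requires finite values")
    if a_arr.var(ddof=1) == 0.0 and b_arr.var(ddof=1) == 0.0:
        if a_arr.mean() == b_arr.mean():
            raise ValueError("t undefined: both groups have zero variance and equal means")
        raise ValueError("t undefined: both groups have zero variance")
    res = stats.ttest_ind(a_arr, b_arr, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """One Welch comparison between two confusion groups on one metric."""

    metric: str
    group_a: ConfusionLabel
    group_b: ConfusionLabel
    n_a: int
    n_b: int
    computable: bool
    reason: str | None = None
    mean_a: float | None = None
    mean_b: float | None = None
    sd_a: float | None = None
    sd_b: float | None = None
    # For log-scale AF comparisons, the natural-scale group means are carried
    # alongside for reporting.
    mean_a_natural: float | None = None
    mean_b_natural: float | None = None
    t_stat: float | None = None
    df: float | None = None
    p_value: float | None = None
    significant_after_bonferroni: bool = False


@dataclass(frozen=True)
class HomozygoteRateRow:
    group: ConfusionLabel
    n_with_homozygote: int
    n_total: int
    rate_percent: float | None  # None when the group is empty

    def __post_init__(self) -> None:
        if self.n_with_homozygote > self.n_total:
            raise ValueError("n_with_homozygote cannot exceed n_total")


_CORE_GROUPS = (
    ConfusionLabel.TP,
    ConfusionLabel.FP,
    ConfusionLabel.TN,
    ConfusionLabel.FN,
)


def _group_members(
    cohort: Sequence[AnnotatedVariant],
) -> dict[ConfusionLabel, list[AnnotatedVariant]]:
    groups: dict[ConfusionLabel, list[AnnotatedVariant]] = {g: [] for g in _CORE_GROUPS}
    for v in cohort:
        label = assign_confusion(v.predicted_class, v.clinical_status)
        if label in groups:
            groups[label].append(v)
    return groups


def compare_groups(
    cohort: Sequence[AnnotatedVariant],
    cfg: DiscriminationConfig | None = None,
) -> list[GroupComparison]:
    """Run the four default Welch comparisons on a confusion-labelled cohort.

    Comparisons (in order): log10 AF TP-vs-FP, log10 AF TN-vs-FN, CADD
    TP-vs-FP, CADD TN-vs-FN. A comparison with fewer than two members in
    either group is reported as not computable rather than raising.
    """
    cfg = cfg or DiscriminationConfig()
    groups = _group_members(cohort)

    def metric_values(members: list[AnnotatedVariant], metric: str) -> np.ndarray:
        if metric == "log10_allele_frequency":
            af = np.array([v.population.allele_frequency for v in members], dtype=float)
            assert (af > 0).all(), "cohort invariant violated: AF must be > 0"
            return np.log10(af)
        if metric == "cadd_phred":
            return np.array([v.population.cadd_phred for v in members], dtype=float)
        raise ValueError(f"unknown metric {metric!r}")

    plan = [
        ("log10_allele_frequency", ConfusionLabel.TP, ConfusionLabel.FP),
        ("log10_allele_frequency", ConfusionLabel.TN, ConfusionLabel.FN),
        ("cadd_phred", ConfusionLabel.TP, ConfusionLabel.FP),
        ("cadd_phred", ConfusionLabel.TN, ConfusionLabel.FN),
    ]

    out: list[GroupComparison] = []
    for metric, ga, gb in plan:
        members_a, members_b = groups[ga], groups[gb]
        base = dict(metric=metric, group_a=ga, group_b=gb,
                    n_a=len(members_a), n_b=len(members_b))
        if len(members_a) < 2 or len(members_b) < 2:
            out.append(GroupComparison(
                computable=False,
                reason="fewer than 2 members in one group",
                **base,
            ))
            continue
        x_a = metric_values(members_a, metric)
        x_b = metric_values(members_b, metric)
        try:
            t, df, p = welch_t(x_a, x_b)
        except ValueError as exc:
            out.append(GroupComparison(computable=False, reason=str(exc), **base))
            continue
        natural_a = natural_b = None
        if metric == "log10_allele_frequency":
            natural_a = float(np.mean([v.population.allele_frequency for v in members_a]))
            natural_b = float(np.mean([v.population.allele_frequency for v in members_b]))
        out.append(GroupComparison(
            computable=True,
            mean_a=float(x_a.mean()), mean_b=float(x_b.mean()),
            sd_a=float(x_a.std(ddof=1)), sd_b=float(x_b.std(ddof=1)),
            mean_a_natural=natural_a, mean_b_natural=natural_b,
            t_stat=t, df=df, p_value=p,
            significant_after_bonferroni=p < cfg.bonferroni_threshold,
            **base,
        ))
    return out


def homozygote_rates(cohort: Sequence[AnnotatedVariant]) -> list[HomozygoteRateRow]:
    """Share of variants with >= 1 reported homozygote, per confusion group."""
    groups = _group_members(cohort)
    rows = []
    for g in _CORE_GROUPS:
        members = groups[g]
        k = sum(1 for v in members if v.population.homozygote_count >= 1)
        n = len(members)
        rows.append(HomozygoteRateRow(
            group=g,
            n_with_homozygote=k,
            n_total=n,
            rate_percent=100.0 * k / n if n else None,
        ))
    return rows


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "metric": c.metric,
            "group_a": c.group_a.value,
            "group_b": c.group_b.value,
            "n_a": c.n_a,
            "n_b": c.n_b,
            "mean_a": c.mean_a,
            "mean_b": c.mean_b,
            "sd_a": c.sd_a,
            "sd_b": c.sd_b,
            "mean_a_natural": c.mean_a_natural,
            "mean_b_natural": c.mean_b_natural,
            "t_stat": c.t_stat,
            "df": c.df,
            "p_value": c.p_value,
            "significant": c.significant_after_bonferroni,
            "computable": c.computable,
            "reason": c.reason or "",
        }
        for c in comparisons
    ])


def rates_to_frame(rows: Sequence[HomozygoteRateRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "group": r.group.value,
            "n_with_homozygote": r.n_with_homozygote,
            "n_total": r.n_total,
            "rate_percent": r.rate_percent if r.rate_percent is not None else math.nan,
        }
        for r in rows
    ])
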