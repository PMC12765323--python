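"""Rule-based suspicion of misclassified predictions; hypomorph profiles.

Population evidence runs counter to some predictions. A predicted-benign
variant that is simultaneously rare, high-CADD, and homozygote-free looks
like a pathogenic variant — a suspected false negative (all three conditions
must hold). A predicted-pathogenic variant that is common, or low-CADD, or
seen in homozygous state looks benign — a suspected false positive (any one
condition suffices). The asymmetry is deliberate: a single benign-like
signal is enough to doubt a pathogenic call, whereas doubting a benign call
requires the full pathogenic-like profile.

The numeric thresholds are tunable operating points, not established
constants: the defaults place the rare/common split around the allele
frequencies observed for concordant pathogenic variants (order 1e-5 to 1e-4)
versus benign ones (above 1e-3), and the CADD split around the conventional
phred-20 deleteriousness mark.

Hypomorphic variants — partial loss-of-function alleles with unusually high
population frequency for a disease allele — are handled by profile
comparison instead: a reference set of known hypomorphs defines a per-metric
min/median/max envelope, and a query variant is judged by whether it falls
inside that envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classification import PredictedClass
from .ingest import AnnotatedVariant, PopulationRecord


@dataclass(frozen=True)
class FlagThresholds:
    af_low_max: float = 1e-4      # AF at or below this counts as "rare"
    af_high_min: float = 1e-3     # AF at or above this counts as "common"
    cadd_high_min: float = 20.0   # CADD at or above this counts as damaging
    cadd_low_max: float = 15.0    # CADD at or below this counts as tolerated
    max_homozygotes_for_fn: int = 0

    def __post_init__(self) -> None:
        if self.af_low_max > self.af_high_min:
            raise ValueError("af_low_max must not exceed af_high_min")
        if self.cadd_low_max > self.cadd_high_min:
            raise ValueError("cadd_low_max must not exceed cadd_high_min")
        if self.max_homozygotes_for_fn < 0:
            raise ValueError("max_homozygotes_for_fn must be >= 0")


class MissingMetricError(ValueError):
    """The variant lacks a population metric the rules need."""


@dataclass(frozen=True)
class SuspicionFlag:
    key: object
    kind: str  # "SUSPECT_FALSE_NEGATIVE" | "SUSPECT_FALSE_POSITIVE" | "NONE"
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind != "NONE" and not self.reasons:
            raise ValueError("a raised flag must carry at least one reason")


def suspect_misclassification(
    v: AnnotatedVariant, th: FlagThresholds | None = None
) -> SuspicionFlag:
    """Apply the directional suspicion rules to one variant.

    Predicted benign: flag as suspected false negative iff AF <= af_low_max
    AND CADD >= cadd_high_min AND homozygotes <= max_homozygotes_for_fn.
    Predicted pathogenic: flag as suspected false positive iff AF >=
    af_high_min OR CADD <= cadd_low_max OR >= 1 homozygote. Ambiguous
    predictions are never flagged.
    """
    th = th or FlagThresholds()
    if v.population is None:
        raise MissingMetricError(f"{v.key}: population metrics missing")
    pop = v.population
    af, cadd, hom = pop.allele_frequency, pop.cadd_phred, pop.homozygote_count

    if v.predicted_class is PredictedClass.BENIGN:
        reasons = []
        if af <= th.af_low_max:
            reasons.append(f"allele frequency {af:g} <= {th.af_low_max:g}")
        if cadd >= th.cadd_high_min:
            reasons.append(f"CADD {cadd:g} >= {th.cadd_high_min:g}")
        if hom <= th.max_homozygotes_for_fn:
            reasons.append(f"homozygotes {hom} <= {th.max_homozygotes_for_fn}")
        if len(reasons) == 3:
            return SuspicionFlag(v.key, "SUSPECT_FALSE_NEGATIVE", tuple(reasons))
        return SuspicionFlag(v.key, "NONE")

    if v.predicted_class is PredictedClass.PATHOGENIC:
        reasons = []
        if af >= th.af_high_min:
            reasons.append(f"allele frequency {af:g} >= {th.af_high_min:g}")
        if cadd <= th.cadd_low_max:
            reasons.append(f"CADD {cadd:g} <= {th.cadd_low_max:g}")
        if hom >= 1:
            reasons.append(f"{hom} homozygote(s) reported")
        if reasons:
            return SuspicionFlag(v.key, "SUSPECT_FALSE_POSITIVE", tuple(reasons))
        return SuspicionFlag(v.key, "NONE")

    return SuspicionFlag(v.key, "NONE")


@dataclass(frozen=True)
class MetricEnvelope:
    minimum: float
    median: float
    maximum: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.median <= self.maximum):
            raise ValueError("envelope requires min <= median <= max")

    def contains(self, value: float) -> bool:
        # Inclusive at both ends: a query matching a reference variant is in range.
        return self.minimum <= value <= self.maximum


@dataclass(frozen=True)
class HypomorphProfile:
    """Per-metric min/median/max envelope over a reference hypomorph set."""

    allele_frequency: MetricEnvelope
    homozygote_count: MetricEnvelope
    cadd_phred: MetricEnvelope
    n_reference: int


def build_profile(references: Sequence[PopulationRecord]) -> HypomorphProfile:
    """Build the envelope from reference variants.

    The median of an even-sized set is the mean of the two central order
    statistics. A single reference collapses the envelope to a point, which
    doubles as a named-comparator mode (is the query like this one variant?).
    """
    if not references:
        raise ValueError("cannot build a profile from an empty reference set")

    def env(values: Sequence[float]) -> MetricEnvelope:
        arr = np.asarray(values, dtype=float)
        return MetricEnvelope(float(arr.min()), float(np.median(arr)), float(arr.max()))

    return HypomorphProfile(
        allele_frequency=env([r.allele_frequency for r in references]),
        homozygote_count=env([r.homozygote_count for r in references]),
        cadd_phred=env([r.cadd_phred for r in references]),
        n_reference=len(references),
    )


@dataclass(frozen=True)
class ProfileComparison:
    per_metric: Mapping[str, bool]
    overall_within: bool


def compare_to_profile(
    query: PopulationRecord, profile: HypomorphProfile
) -> ProfileComparison:
    """Inclusive range check of a query variant against the profile envelope."""
    per_metric = {
        "allele_frequency": profile.allele_frequency.contains(query.allele_frequency),
        "homozygote_count": profile.homozygote_count.contains(query.homozygote_count),
        "cadd_phred": profile.cadd_phred.contains(query.cadd_phred),
    }
    return ProfileComparison(per_metric=per_metric, overall_within=all(per_metric.values()))
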