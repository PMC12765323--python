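"""Score thresholding and clinical-label collapsing.

Predictor scores in [0, 1] are mapped to a three-way call — likely benign,
ambiguous, likely pathogenic — using the predictor's published decision
thresholds. Clinical assertions are collapsed into a binary
pathogenic/benign label, with everything non-definitive (VUS, conflicting
interpretations, missing assertion criteria) treated as ineligible for
benchmarking rather than as an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class PredictedClass(Enum):
    """Three-way predictor call over the score range [0, 1]."""

    BENIGN = "benign"
    AMBIGUOUS = "ambiguous"
    PATHOGENIC = "pathogenic"


class CollapsedLabel(Enum):
    """Binary clinical label, or ineligible when no definitive assertion exists."""

    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    INELIGIBLE = "ineligible"


class ClinicalStatus(Enum):
    """Clinical annotation state of a cohort member."""

    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    INELIGIBLE = "ineligible"
    ABSENT = "absent"

    @classmethod
    def from_collapsed(cls, label: CollapsedLabel) -> "ClinicalStatus":
        return cls(label.value)


@dataclass(frozen=True)
class ClassifierConfig:
    """Score thresholds for the three-way call.

    ``benign_max`` is the exclusive upper bound of the benign class and
    ``pathogenic_min`` the exclusive lower bound of the pathogenic class:
    benign iff score < benign_max, pathogenic iff score > pathogenic_min,
    ambiguous otherwise. Defaults are the predictor's published operating
    points (benign below 0.34, pathogenic above 0.564), stated to three
    decimals; the continuous rule leaves no score unassigned.
    """

    benign_max: float = 0.34
    pathogenic_min: float = 0.564

    def __post_init__(self) -> None:
        if not (0.0 < self.benign_max <= self.pathogenic_min < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < benign_max <= pathogenic_min < 1, "
                f"got benign_max={self.benign_max}, pathogenic_min={self.pathogenic_min}"
            )


def classify_score(score: float, cfg: ClassifierConfig | None = None) -> PredictedClass:
    """Map a pathogenicity score in [0, 1] to a three-way predicted class."""
    cfg = cfg or ClassifierConfig()
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score must lie in [0, 1], got {score}")
    if score < cfg.benign_max:
        return PredictedClass.BENIGN
    if score > cfg.pathogenic_min:
        return PredictedClass.PATHOGENIC
    return PredictedClass.AMBIGUOUS


_PATHOGENIC_TERMS = {"pathogenic", "likely pathogenic"}
_BENIGN_TERMS = {"benign", "likely benign"}


def _normalize_terms(raw_label: str) -> list[str]:
    # Composite submissions arrive as "Pathogenic/Likely pathogenic" or with
    # semicolon separators; split and judge each term.
    cleaned = raw_label.strip().lower().replace("_", " ")
    parts = [p.strip() for sep in (";",) for p in cleaned.split(sep)]
    terms: list[str] = []
    for part in parts:
        terms.extend(t.strip() for t in part.split("/") if t.strip())
    return terms or [cleaned]


def collapse_with_reason(
    raw_label: str, stars: int, min_stars: int = 1
) -> tuple[CollapsedLabel, str | None]:
    """Collapse a raw clinical label, returning the ineligibility reason if any.

    Labels are matched case-insensitively; composite labels collapse when all
    their parts agree on a side. Records below ``min_stars`` review stars are
    ineligible regardless of label (assertion criteria are required).
    """
    if not raw_label or not raw_label.strip():
        raise ValueError("raw clinical label must be non-empty")
    terms = _normalize_terms(raw_label)
    if all(t in _PATHOGENIC_TERMS for t in terms):
        label = CollapsedLabel.PATHOGENIC
    elif all(t in _BENIGN_TERMS for t in terms):
        label = CollapsedLabel.BENIGN
    else:
        return CollapsedLabel.INELIGIBLE, f"non-definitive label {raw_label!r}"
    if stars < min_stars:
        return (
            CollapsedLabel.INELIGIBLE,
            f"review stars {stars} below required {min_stars}",
        )
    return label, None


def collapse_clinical(raw_label: str, stars: int, min_stars: int = 1) -> CollapsedLabel:
    """Collapse a raw clinical significance label into the binary benchmark label."""
    label, _ = collapse_with_reason(raw_label, stars, min_stars)
    return label
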