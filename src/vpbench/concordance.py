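"""Confusion labelling of predictions against binary clinical labels.

Each clinically definitive variant receives one of six confusion labels:
true/false positive/negative plus two ambiguous buckets (ambiguous prediction
on a pathogenic-labelled variant, ambiguous on a benign-labelled one). The
ambiguous buckets are kept separate so downstream metrics can either exclude
them (primary analysis) or count them as errors (sensitivity analysis).
Variants without a definitive label are not evaluable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .classification import ClinicalStatus, CollapsedLabel, PredictedClass
from .ingest import AnnotatedVariant


class ConfusionLabel(Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"
    AMBIG_ON_PATHOGENIC = "AMBIG_P"
    AMBIG_ON_BENIGN = "AMBIG_B"
    NOT_EVALUABLE = "NOT_EVALUABLE"


def assign_confusion(
    predicted: PredictedClass,
    clinical: ClinicalStatus | CollapsedLabel,
) -> ConfusionLabel:
    """The 3x2 confusion mapping; non-definitive clinical states are not evaluable."""
    status = clinical.value if isinstance(clinical, (ClinicalStatus, CollapsedLabel)) else clinical
    if status == "pathogenic":
        return {
            PredictedClass.PATHOGENIC: ConfusionLabel.TP,
            PredictedClass.BENIGN: ConfusionLabel.FN,
            PredictedClass.AMBIGUOUS: ConfusionLabel.AMBIG_ON_PATHOGENIC,
        }[predicted]
    if status == "benign":
        return {
            PredictedClass.PATHOGENIC: ConfusionLabel.FP,
            PredictedClass.BENIGN: ConfusionLabel.TN,
            PredictedClass.AMBIGUOUS: ConfusionLabel.AMBIG_ON_BENIGN,
        }[predicted]
    return ConfusionLabel.NOT_EVALUABLE


@dataclass(frozen=True)
class ConfusionTable:
    """Confusion counts at cohort scope or for a single gene."""

    scope: str
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    ambig_p: int = 0
    ambig_b: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "ambig_p", "ambig_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_pathogenic_labelled(self) -> int:
        return self.tp + self.fn + self.ambig_p

    @property
    def n_benign_labelled(self) -> int:
        return self.tn + self.fp + self.ambig_b

    @property
    def n_evaluable(self) -> int:
        return self.n_pathogenic_labelled + self.n_benign_labelled


def tabulate(
    cohort: Sequence[AnnotatedVariant], by_gene: bool = False
) -> list[ConfusionTable]:
    """Tabulate confusion counts for the whole cohort and optionally per gene.

    Returns the cohort-scope table first, then (if ``by_gene``) one table per
    gene with at least one evaluable member, sorted by gene symbol. Per-gene
    counts sum to the cohort counts by construction. An empty cohort yields
    an empty list.
    """
    if not cohort:
        return []

    counters: dict[str, dict[ConfusionLabel, int]] = {}
    cohort_counter: dict[ConfusionLabel, int] = {}
    for v in cohort:
        label = assign_confusion(v.predicted_class, v.clinical_status)
        cohort_counter[label] = cohort_counter.get(label, 0) + 1
        gene_counter = counters.setdefault(v.key.gene, {})
        gene_counter[label] = gene_counter.get(label, 0) + 1

    def build(scope: str, counter: dict[ConfusionLabel, int]) -> ConfusionTable:
        return ConfusionTable(
            scope=scope,
            tp=counter.get(ConfusionLabel.TP, 0),
            fp=counter.get(ConfusionLabel.FP, 0),
            tn=counter.get(ConfusionLabel.TN, 0),
            fn=counter.get(ConfusionLabel.FN, 0),
            ambig_p=counter.get(ConfusionLabel.AMBIG_ON_PATHOGENIC, 0),
            ambig_b=counter.get(ConfusionLabel.AMBIG_ON_BENIGN, 0),
        )

    tables = [build("cohort", cohort_counter)]
    if by_gene:
        for gene in sorted(counters):
            table = build(gene, counters[gene])
            if table.n_evaluable > 0:
                tables.append(table)
    return tables


def tables_to_frame(tables: Sequence[ConfusionTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": t.scope,
                "tp": t.tp,
                "fp": t.fp,
                "tn": t.tn,
                "fn": t.fn,
                "ambig_p": t.ambig_p,
                "ambig_b": t.ambig_b,
            }
            for t in tables
        ],
        columns=["scope", "tp", "fp", "tn", "fn", "ambig_p", "ambig_b"],
    )
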