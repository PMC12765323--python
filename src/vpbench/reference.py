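"""Published reference counts for the 107-gene IRD panel benchmark.

These constants re-type the printed summary tables of a ClinVar-vs-predictor
concordance benchmark over inherited-retinal-disease genes: the cohort-level
confusion counts, the per-gene counts for the 20 most commonly implicated
genes, the homozygote-rate table, and the nine well-characterized ABCA4
hypomorphic variants with their scores and population metrics. They serve as
in-package worked-example inputs — the validation suite recomputes every
derived figure (sensitivity, specificity, FDR, confidence intervals, macro
and micro panel summaries, homozygote rates, profile envelopes) from these
raw counts through the same code paths used for any cohort.
"""

from __future__ import annotations

from .concordance import ConfusionTable
from .ingest import PopulationRecord
from .variant_model import make_key

#: Cohort-level confusion counts over the 4204 clinically definitive variants.
COHORT_CONFUSION = ConfusionTable(
    scope="cohort", tp=1252, fn=325, ambig_p=219, tn=2115, fp=133, ambig_b=160
)

#: Three-way predicted-class counts over the full population-present cohort.
COHORT_CLASS_COUNTS = {"benign": 89_408, "ambiguous": 12_248, "pathogenic": 26_592}
COHORT_TOTAL = 128_248

#: Clinically definitive label counts feeding the confusion table.
CLINVAR_DEFINITIVE = {"pathogenic": 1_796, "benign": 2_408}

#: Per-gene confusion counts (gene, tp, fn, tn, fp) for the 20 most commonly
#: implicated IRD genes. Ambiguous predictions are already excluded.
TOP20_GENE_COUNTS: list[tuple[str, int, int, int, int]] = [
    ("ABCA4", 217, 80, 22, 0),
    ("USH2A", 97, 46, 118, 0),
    ("RPGR", 1, 1, 34, 0),
    ("PRPH2", 29, 8, 1, 0),
    ("BEST1", 50, 10, 6, 1),
    ("RS1", 23, 1, 7, 0),
    ("RP1", 5, 1, 28, 1),
    ("RHO", 29, 4, 5, 1),
    ("CHM", 1, 0, 24, 3),
    ("CRB1", 44, 26, 14, 1),
    ("PRPF31", 1, 0, 0, 0),
    ("MYO7A", 83, 3, 29, 5),
    ("OPA1", 1, 0, 13, 3),
    ("CNGB3", 8, 2, 18, 1),
    ("RPE65", 59, 5, 5, 1),
    ("EYS", 9, 4, 43, 1),
    ("GUCY2D", 19, 1, 13, 0),
    ("PROM1", 0, 3, 5, 1),
    ("CNGA3", 50, 10, 15, 0),
    ("RDH12", 28, 6, 2, 0),
]


def top20_confusion_tables() -> list[ConfusionTable]:
    return [
        ConfusionTable(scope=gene, tp=tp, fn=fn, tn=tn, fp=fp)
        for gene, tp, fn, tn, fp in TOP20_GENE_COUNTS
    ]


#: Homozygote-rate inputs: confusion group -> (variants with >= 1 homozygote, total).
HOMOZYGOTE_COUNTS = {
    "TP": (19, 1252),
    "FP": (40, 133),
    "TN": (1010, 2115),
    "FN": (14, 325),
}

#: Nine well-characterized ABCA4 hypomorphic variants:
#: (protein change, predictor score, allele frequency, homozygotes, CADD phred).
ABCA4_HYPOMORPHS: list[tuple[str, float, float, int, float]] = [
    ("Gly863Ala", 0.343, 7.06e-3, 46, 31.0),
    ("Ala1038Val", 0.164, 1.85e-3, 7, 19.9),
    ("Pro1486Leu", 0.201, 3.79e-5, 0, 24.8),
    ("Thr1526Met", 0.366, 1.23e-4, 0, 25.2),
    ("Ile1562Thr", 0.180, 1.56e-3, 3, 22.9),
    ("Asn1868Ile", 0.223, 5.58e-2, 2989, 23.3),
    ("Gly1961Glu", 0.853, 3.41e-3, 44, 26.2),
    ("Arg2030Gln", 0.106, 4.77e-4, 0, 27.2),
    ("Arg2107His", 0.326, 1.15e-3, 17, 29.3),
]

#: The haplotype-phased candidate hypomorph queried against the envelope.
PRO1948LEU = ("Pro1948Leu", 3.93e-2, 1534, 23.5)


def hypomorph_population_records(
    exclude: str | None = None,
) -> list[PopulationRecord]:
    """The ABCA4 hypomorph reference set as population records.

    ``exclude`` drops one variant by protein change (e.g. the one hypomorph
    the predictor scores as pathogenic, when profiling the remaining eight).
    """
    return [
        PopulationRecord(make_key("ABCA4", change), af, hom, cadd)
        for change, _score, af, hom, cadd in ABCA4_HYPOMORPHS
        if change != exclude
    ]


def pro1948leu_record() -> PopulationRecord:
    change, af, hom, cadd = PRO1948LEU
    return PopulationRecord(make_key("ABCA4", change), af, hom, cadd)
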