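"""Readers for the three tabular inputs and cohort assembly.

Three TSV tables feed the benchmark: a predictor score table (one
pathogenicity score per missense variant), a clinical annotation table
(significance label plus review stars), and a population metrics table
(allele frequency, homozygote count, CADD phred). The analysis cohort is the
inner join of predictor and population records — a variant without population
data carries no allele frequency or homozygote evidence and is excluded, so
every cohort member has allele_frequency > 0. Clinical labels are attached
where they match; their absence is a state, not an error.

Column names follow fixed defaults (see ``DEFAULT_SCHEMAS``) and can be
remapped through the YAML run configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classification import (
    ClassifierConfig,
    ClinicalStatus,
    PredictedClass,
    classify_score,
    collapse_with_reason,
)
from .variant_model import (
    MatchReport,
    ProteinChangeError,
    VariantKey,
    make_key,
    match_records,
    parse_protein_change,
)

logger = logging.getLogger(__name__)

DEFAULT_SCHEMAS: dict[str, dict[str, str]] = {
    "predictor": {
        "gene": "gene",
        "protein_change": "protein_variant",
        "score": "am_pathogenicity",
    },
    "clinical": {
        "gene": "gene",
        "protein_change": "protein_change",
        "label": "clinical_significance",
        "stars": "review_stars",
    },
    "population": {
        "gene": "gene",
        "protein_change": "protein_change",
        "allele_frequency": "allele_frequency",
        "homozygote_count": "homozygote_count",
        "cadd_phred": "cadd_phred",
    },
}

#: Optional predictor columns carried as annotation when present.
OPTIONAL_PREDICTOR_COLUMNS = ("chrom", "pos", "ref", "alt", "transcript")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A row holds a value outside its declared domain."""


class EmptyCohortError(ValueError):
    """Predictor and population tables share no variants."""


@dataclass(frozen=True)
class PredictorRecord:
    key: VariantKey
    score: float
    chrom: str | None = None
    pos: int | None = None  # 1-based GRCh38; annotation only, never a join key
    ref: str | None = None
    alt: str | None = None
    transcript: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass(frozen=True)
class ClinicalRecord:
    key: VariantKey
    raw_label: str
    stars: int

    def __post_init__(self) -> None:
        if self.stars not in (0, 1, 2, 3, 4):
            raise ValueError(f"review stars must be in 0..4, got {self.stars}")


@dataclass(frozen=True)
class PopulationRecord:
    key: VariantKey
    allele_frequency: float
    homozygote_count: int
    cadd_phred: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError(
                f"allele frequency must lie in [0, 1], got {self.allele_frequency}"
            )
        if self.homozygote_count < 0:
            raise ValueError(f"homozygote count must be >= 0, got {self.homozygote_count}")
        if self.cadd_phred < 0:
            raise ValueError(f"CADD phred must be >= 0, got {self.cadd_phred}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One cohort member: score, predicted class, clinical state, population metrics."""

    key: VariantKey
    score: float
    predicted_class: PredictedClass
    clinical_status: ClinicalStatus
    population: PopulationRecord
    raw_label: str | None = None
    stars: int | None = None
    ineligible_reason: str | None = field(default=None, compare=False)


def _read_tsv(path: str | Path, schema: Mapping[str, str], table_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, skip_blank_lines=True)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise SchemaError(
            f"{table_name} table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    return df


def _to_float(raw: str, what: str, row: int) -> float:
    try:
        return float(str(raw).replace(",", ""))
    except (TypeError, ValueError) as exc:
        raise RowError(f"data row {row}: cannot parse {what} from {raw!r}") from exc


def _to_int(raw: str, what: str, row: int) -> int:
    try:
        return int(float(str(raw).replace(",", "")))
    except (TypeError, ValueError) as exc:
        raise RowError(f"data row {row}: cannot parse {what} from {raw!r}") from exc


def read_predictor_table(
    path: str | Path,
    panel: Iterable[str],
    schema: Mapping[str, str] | None = None,
) -> list[PredictorRecord]:
    """Read predictor scores, keeping only genes in the panel.

    Rows whose protein change is not a parseable missense substitution are
    skipped with a log message; a score outside [0, 1] is a hard row error
    (data row numbers count non-comment rows after the header, 1-based).
    Duplicate keys keep the first record, mirroring one score per variant per
    representative transcript.
    """
    schema = {**DEFAULT_SCHEMAS["predictor"], **(schema or {})}
    panel_upper = {g.strip().upper() for g in panel}
    df = _read_tsv(path, schema, "predictor")

    records: list[PredictorRecord] = []
    seen: set[VariantKey] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        gene = str(rowd[schema["gene"]]).strip().upper()
        if gene not in panel_upper:
            continue
        score = _to_float(rowd[schema["score"]], "score", i)
        if not (0.0 <= score <= 1.0):
            raise RowError(f"data row {i}: score {score} outside [0, 1]")
        try:
            key = make_key(gene, str(rowd[schema["protein_change"]]))
        except ProteinChangeError as exc:
            logger.info("predictor data row %d skipped: %s", i, exc)
            continue
        if key in seen:
            logger.info("predictor data row %d: duplicate key %s, keeping first", i, key)
            continue
        seen.add(key)
        extras = {
            name: (str(rowd[name]) if pd.notna(rowd.get(name)) else None)
            for name in OPTIONAL_PREDICTOR_COLUMNS
            if name in df.columns
        }
        if extras.get("pos") is not None:
            extras["pos"] = _to_int(extras["pos"], "pos", i)
        records.append(PredictorRecord(key=key, score=score, **extras))
    return records


def read_clinical_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[ClinicalRecord]:
    """Read clinical annotations; raw labels are preserved verbatim.

    Rows with unparseable protein changes are skipped and logged (clinical
    sources routinely carry nonsense/frameshift changes that are simply not
    part of a missense benchmark).
    """
    schema = {**DEFAULT_SCHEMAS["clinical"], **(schema or {})}
    df = _read_tsv(path, schema, "clinical")

    records: list[ClinicalRecord] = []
    seen: set[VariantKey] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            key = make_key(str(rowd[schema["gene"]]), str(rowd[schema["protein_change"]]))
        except (ProteinChangeError, ValueError) as exc:
            logger.info("clinical data row %d skipped: %s", i, exc)
            continue
        stars = _to_int(rowd[schema["stars"]], "review stars", i)
        if stars not in (0, 1, 2, 3, 4):
            raise RowError(f"data row {i}: review stars {stars} outside 0..4")
        if key in seen:
            logger.info("clinical data row %d: duplicate key %s, keeping first", i, key)
            continue
        seen.add(key)
        records.append(ClinicalRecord(key=key, raw_label=str(rowd[schema["label"]]), stars=stars))
    return records


def read_population_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[PopulationRecord]:
    """Read population metrics (allele frequency, homozygote count, CADD phred)."""
    schema = {**DEFAULT_SCHEMAS["population"], **(schema or {})}
    df = _read_tsv(path, schema, "population")

    records: list[PopulationRecord] = []
    seen: set[VariantKey] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            key = make_key(str(rowd[schema["gene"]]), str(rowd[schema["protein_change"]]))
        except (ProteinChangeError, ValueError) as exc:
            logger.info("population data row %d skipped: %s", i, exc)
            continue
        af = _to_float(rowd[schema["allele_frequency"]], "allele frequency", i)
        hom = _to_int(rowd[schema["homozygote_count"]], "homozygote count", i)
        cadd = _to_float(rowd[schema["cadd_phred"]], "CADD phred", i)
        try:
            record = PopulationRecord(key, af, hom, cadd)
        except ValueError as exc:
            raise RowError(f"data row {i}: {exc}") from exc
        if key in seen:
            logger.info("population data row %d: duplicate key %s, keeping first", i, key)
            continue
        seen.add(key)
        records.append(record)
    return records


def assemble_cohort(
    predictor: Sequence[PredictorRecord],
    clinical: Sequence[ClinicalRecord],
    population: Sequence[PopulationRecord],
    overrides: Mapping[VariantKey, VariantKey] | None = None,
    classifier: ClassifierConfig | None = None,
    min_stars: int = 1,
) -> tuple[list[AnnotatedVariant], MatchReport]:
    """Assemble the analysis cohort: predictor ∩ population, clinical attached.

    The cohort is the inner join of predictor and population records on the
    variant key (population presence is the inclusion criterion). Clinical
    records are matched against cohort keys — with ``overrides`` standing in
    for manual transcript reconciliation — and collapsed to a binary label;
    unmatched members get clinical status ``ABSENT``.

    Returns the cohort in deterministic key order plus the clinical
    :class:`~vpbench.variant_model.MatchReport`.
    """
    classifier = classifier or ClassifierConfig()
    pop_by_key = {r.key: r for r in population}
    pred_by_key = {r.key: r for r in predictor}
    cohort_keys = sorted(set(pred_by_key) & set(pop_by_key))
    if not cohort_keys:
        raise EmptyCohortError(
            "empty cohort: no variant is present in both the predictor and "
            "population tables"
        )
    dropped = len(pred_by_key) - len(cohort_keys)
    if dropped:
        logger.info("%d predictor variants lack population data and are excluded", dropped)

    clin_by_key = {r.key: r for r in clinical}
    pairs, report = match_records(set(cohort_keys), set(clin_by_key), overrides)
    clin_for_cohort: dict[VariantKey, ClinicalRecord] = {
        pk: clin_by_key[ck] for ck, pk in pairs
    }

    cohort: list[AnnotatedVariant] = []
    for key in cohort_keys:
        pop = pop_by_key[key]
        if pop.allele_frequency <= 0.0:
            raise RowError(
                f"{key}: allele frequency must be > 0 for population-present variants"
            )
        score = pred_by_key[key].score
        clin = clin_for_cohort.get(key)
        if clin is None:
            status, reason, raw, stars = ClinicalStatus.ABSENT, None, None, None
        else:
            collapsed, reason = collapse_with_reason(clin.raw_label, clin.stars, min_stars)
            status = ClinicalStatus.from_collapsed(collapsed)
            raw, stars = clin.raw_label, clin.stars
        cohort.append(
            AnnotatedVariant(
                key=key,
                score=score,
                predicted_class=classify_score(score, classifier),
                clinical_status=status,
                population=pop,
                raw_label=raw,
                stars=stars,
                ineligible_reason=reason,
            )
        )
    return cohort, report


COHORT_COLUMNS = (
    "gene",
    "protein_change",
    "score",
    "predicted_class",
    "clinical_status",
    "raw_label",
    "stars",
    "allele_frequency",
    "homozygote_count",
    "cadd_phred",
)


def cohort_to_frame(cohort: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    """Flatten a cohort into a DataFrame with a stable column order."""
    rows = [
        {
            "gene": v.key.gene,
            "protein_change": v.key.substitution.short(),
            "score": v.score,
            "predicted_class": v.predicted_class.value,
            "clinical_status": v.clinical_status.value,
            "raw_label": v.raw_label if v.raw_label is not None else "",
            "stars": v.stars if v.stars is not None else "",
            "allele_frequency": v.population.allele_frequency,
            "homozygote_count": v.population.homozygote_count,
            "cadd_phred": v.population.cadd_phred,
        }
        for v in cohort
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(cohort: Sequence[AnnotatedVariant], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> list[AnnotatedVariant]:
    """Read back a cohort TSV written by :func:`write_cohort` (round-trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing column(s): {', '.join(missing)}")
    cohort: list[AnnotatedVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        key = make_key(rowd["gene"], rowd["protein_change"])
        pop = PopulationRecord(
            key,
            _to_float(rowd["allele_frequency"], "allele frequency", i),
            _to_int(rowd["homozygote_count"], "homozygote count", i),
            _to_float(rowd["cadd_phred"], "CADD phred", i),
        )
        cohort.append(
            AnnotatedVariant(
                key=key,
                score=_to_float(rowd["score"], "score", i),
                predicted_class=PredictedClass(rowd["predicted_class"]),
                clinical_status=ClinicalStatus(rowd["clinical_status"]),
                population=pop,
                raw_label=rowd["raw_label"] or None,
                stars=_to_int(rowd["stars"], "stars", i) if rowd["stars"] != "" else None,
            )
        )
    return cohort
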