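"""End-to-end benchmark orchestration: ingest, classify, score, discriminate, flag.

``run_benchmark`` drives the whole analysis from a :class:`RunConfig` and
writes a report bundle: the assembled cohort, confusion tables (cohort and
per gene), performance reports under both ambiguous policies, a panel
summary, the four Welch group comparisons, homozygote rates, suspicion
flags, and a machine-readable summary JSON that also carries the filtering
funnel (how many variants survived each step), so the cohort construction is
auditable. Identical inputs and config produce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import ingest
from .classification import ClassifierConfig, ClinicalStatus
from .concordance import tables_to_frame, tabulate
from .discrimination import (
    DiscriminationConfig,
    compare_groups,
    comparisons_to_frame,
    homozygote_rates,
    rates_to_frame,
)
from .flagger import FlagThresholds, suspect_misclassification
from .performance import (
    AmbiguousPolicy,
    MacroRule,
    MetricConfig,
    PanelSummary,
    PerformanceReport,
    panel_summary,
    performance_metrics,
    reports_to_frame,
    roc_pr,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is invalid (missing paths, bad values)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass(frozen=True)
class RunConfig:
    predictor_path: Path
    clinical_path: Path
    population_path: Path
    panel_path: Path
    out_dir: Path
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    discrimination: DiscriminationConfig = field(default_factory=DiscriminationConfig)
    flags: FlagThresholds = field(default_factory=FlagThresholds)
    min_stars: int = 1
    macro_rule: MacroRule = MacroRule.DEFINED_ONLY
    schemas: Mapping[str, Mapping[str, str]] | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("predictor_path", "clinical_path", "population_path", "panel_path"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigError(f"{name} does not exist: {path}")
        if self.min_stars < 0:
            raise ConfigError("min_stars must be >= 0")


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file; keyword overrides win.

    Recognized YAML sections: ``inputs`` (predictor/clinical/population/panel
    paths and out_dir), ``classifier`` (benign_max, pathogenic_min),
    ``clinical`` (min_stars), ``metrics`` (confidence), ``discrimination``
    (alpha, n_comparisons), ``flagger`` (threshold fields), ``schemas``.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc

    inputs = raw.get("inputs", {})
    base = Path(path).parent

    def respath(key: str) -> Path:
        if key in overrides and overrides[key] is not None:
            return Path(overrides[key])
        if key not in inputs:
            raise ConfigError(f"config {path} missing inputs.{key}")
        p = Path(inputs[key])
        return p if p.is_absolute() else base / p

    try:
        classifier = ClassifierConfig(**raw.get("classifier", {}))
        metrics = MetricConfig(confidence=raw.get("metrics", {}).get("confidence", 0.95))
        discrimination = DiscriminationConfig(**raw.get("discrimination", {}))
        flags = FlagThresholds(**raw.get("flagger", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config value: {exc}") from exc

    return RunConfig(
        predictor_path=respath("predictor"),
        clinical_path=respath("clinical"),
        population_path=respath("population"),
        panel_path=respath("panel"),
        out_dir=Path(overrides.get("out_dir") or inputs.get("out_dir", "vpbench_out")),
        classifier=classifier,
        metrics=metrics,
        discrimination=discrimination,
        flags=flags,
        min_stars=raw.get("clinical", {}).get("min_stars", 1),
        schemas=raw.get("schemas"),
    )


def read_panel(path: str | Path) -> set[str]:
    """Read a gene panel file: one symbol per line, ``#`` comments allowed."""
    panel = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            panel.add(line.upper())
    if not panel:
        raise ConfigError(f"panel file {path} contains no gene symbols")
    return panel


@dataclass(frozen=True)
class BenchmarkResult:
    out_dir: Path
    summary: dict
    cohort_size: int
    evaluable: int


def _report_json(r: PerformanceReport) -> dict:
    def prop(p):
        if p is None:
            return None
        return {"value": p.value, "lower": p.lower, "upper": p.upper, "k": p.k, "n": p.n}

    return {
        "scope": r.scope,
        "policy": r.policy.value,
        "sensitivity": prop(r.sensitivity),
        "specificity": prop(r.specificity),
        "fdr": prop(r.fdr),
        "undefined": list(r.undefined_reasons),
    }


def _summary_json(s: PanelSummary) -> dict:
    return {
        "macro_sensitivity": s.macro_sensitivity,
        "macro_specificity": s.macro_specificity,
        "micro_fdr": s.micro_fdr,
        "genes_in_macro_sensitivity": s.genes_in_macro_sensitivity,
        "genes_in_macro_specificity": s.genes_in_macro_specificity,
        "genes_in_micro_fdr": s.genes_in_micro_fdr,
    }


def run_benchmark(cfg: RunConfig) -> BenchmarkResult:
    """Execute the full benchmark and write the report bundle to ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schemas = cfg.schemas or {}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("ingest")
    try:
        panel = read_panel(cfg.panel_path)
        predictor = ingest.read_predictor_table(
            cfg.predictor_path, panel, schemas.get("predictor")
        )
        clinical = ingest.read_clinical_table(cfg.clinical_path, schemas.get("clinical"))
        population = ingest.read_population_table(
            cfg.population_path, schemas.get("population")
        )

        current = stage("assemble")
        cohort, match_report = ingest.assemble_cohort(
            predictor, clinical, population,
            classifier=cfg.classifier, min_stars=cfg.min_stars,
        )
        ingest.write_cohort(cohort, out / "cohort.tsv")

        current = stage("concordance")
        tables = tabulate(cohort, by_gene=True)
        tables_to_frame(tables).to_csv(out / "confusion.tsv", sep="\t", index=False)
        cohort_table, gene_tables = tables[0], tables[1:]

        current = stage("performance")
        reports_by_policy = {}
        for policy in AmbiguousPolicy:
            mc = MetricConfig(confidence=cfg.metrics.confidence, ambiguous_policy=policy)
            reports_by_policy[policy] = {
                "cohort": performance_metrics(cohort_table, mc),
                "genes": [performance_metrics(t, mc) for t in gene_tables],
            }
        exclude_reports = reports_by_policy[AmbiguousPolicy.EXCLUDE]
        reports_to_frame(
            exclude_reports["genes"], gene_tables
        ).to_csv(out / "per_gene_report.tsv", sep="\t", index=False)
        summary_by_policy = {
            policy.value: _report_json(rep["cohort"])
            for policy, rep in reports_by_policy.items()
        }
        panel_sum = (
            _summary_json(panel_summary(exclude_reports["genes"], cfg.macro_rule))
            if gene_tables
            else None
        )

        definitive = [
            v for v in cohort
            if v.clinical_status in (ClinicalStatus.PATHOGENIC, ClinicalStatus.BENIGN)
        ]
        auroc = auprc = None
        if definitive and len({v.clinical_status for v in definitive}) == 2:
            auroc, auprc = roc_pr(
                [v.score for v in definitive],
                [v.clinical_status for v in definitive],
            )

        current = stage("discrimination")
        comparisons = compare_groups(cohort, cfg.discrimination)
        comparisons_to_frame(comparisons).to_csv(
            out / "discrimination.tsv", sep="\t", index=False
        )
        rates = homozygote_rates(cohort)
        rates_to_frame(rates).to_csv(out / "homozygote_rates.tsv", sep="\t", index=False)

        current = stage("flagger")
        flags = [suspect_misclassification(v, cfg.flags) for v in cohort]
        flag_rows = [
            {"gene": v.key.gene, "protein_change": v.key.substitution.short(),
             "kind": f.kind, "reasons": "; ".join(f.reasons)}
            for v, f in zip(cohort, flags)
        ]
        pd.DataFrame(
            flag_rows, columns=["gene", "protein_change", "kind", "reasons"]
        ).to_csv(out / "flags.tsv", sep="\t", index=False)

    except ingest.EmptyCohortError as exc:
        raise StageError(f"stage {current}: {exc}") from exc
    except (ingest.SchemaError, ingest.RowError) as exc:
        raise StageError(f"stage {current}: {exc}") from exc

    funnel = {
        "predictor_in_panel": len(predictor),
        "population_records": len(population),
        "cohort_population_present": len(cohort),
        "clinical_records_offered": len(clinical),
        "clinical_matched": match_report.matched,
        "clinical_unmatched": match_report.unmatched_clinical,
        "clinically_definitive": len(definitive),
        "ambiguous_among_definitive": cohort_table.ambig_p + cohort_table.ambig_b,
        "evaluable_after_ambiguous_exclusion": (
            cohort_table.tp + cohort_table.fn + cohort_table.tn + cohort_table.fp
        ),
    }
    for name, count in funnel.items():
        logger.info("funnel: %s = %d", name, count)
    if not definitive:
        logger.warning("ran, but no clinically definitive variants were evaluable")

    summary = {
        "funnel": funnel,
        "cohort_metrics": summary_by_policy,
        "panel_summary": panel_sum,
        "auroc": auroc,
        "auprc": auprc,
        "n_suspect_false_negative": sum(
            1 for f in flags if f.kind == "SUSPECT_FALSE_NEGATIVE"
        ),
        "n_suspect_false_positive": sum(
            1 for f in flags if f.kind == "SUSPECT_FALSE_POSITIVE"
        ),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return BenchmarkResult(
        out_dir=out,
        summary=summary,
        cohort_size=len(cohort),
        evaluable=len(definitive),
    )
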