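"""Seeded synthetic variant cohorts with known truth, plus closed-form expectations.

The generator emits the three input tables the benchmark consumes —
predictor scores, clinical annotations, population metrics — for a cohort of
synthetic missense variants whose truth class (pathogenic/benign) is drawn
first and drives everything else:

* scores: class-conditional Beta distributions; the defaults were fitted so
  that the three-way call on each truth class reproduces the class shares a
  panel-scale benchmark exhibits (about 70% of truth-pathogenic variants
  called pathogenic, 18% benign, 12% ambiguous, and the mirror-image
  structure for truth-benign variants);
* clinical labels: a definitive label is attached with a class-conditional
  probability (clinical databases annotate suspected-pathogenic variants far
  more densely than benign background variation), with a configurable
  label-error (flip) rate, review stars drawn from a categorical
  distribution, and a slice of variants labelled as VUS;
* allele frequency: class-conditional truncated normals on the log10 scale,
  bounded to [-8, 0] so every variant is population-present (AF > 0),
  matching the cohort inclusion rule;
* CADD phred: class-conditional truncated normals bounded below at 0;
* homozygote counts: Binomial(N, AF^2), the Hardy–Weinberg expectation for a
  reference population of N individuals.

Because the score model is analytic, the benchmark's operating
characteristics have closed forms (:func:`expected_metrics`), which the
recovery tests compare against the full pipeline estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .classification import ClassifierConfig
from .variant_model import _ONE_TO_THREE, CANONICAL_AA


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate a panel-scale benchmark.

    The default cohort size (107 genes x 1200 variants = 128 400) mirrors the
    scale of a full gene-panel score release restricted to
    population-present variants; tests use much smaller sizes through the
    same contract.
    """

    seed: int = 0
    n_genes: int = 107
    variants_per_gene: int = 1200
    p_truth_pathogenic: float = 0.2
    # Score model (class-conditional Beta), fitted to panel-scale class shares.
    a_p: float = 0.81
    b_p: float = 0.35
    a_b: float = 0.18
    b_b: float = 1.41
    # Annotation model.
    p_labeled_pathogenic: float = 0.35
    p_labeled_benign: float = 0.12
    p_vus: float = 0.08  # additional share labelled as VUS (ineligible)
    label_error_rate: float = 0.0
    star_probs: tuple[float, ...] = (0.05, 0.45, 0.35, 0.10, 0.05)
    # log10 allele frequency, truncated normal on [-8, 0].
    af_mu_pathogenic: float = -4.7
    af_sd_pathogenic: float = 1.0
    af_mu_benign: float = -3.0
    af_sd_benign: float = 1.5
    af_bounds: tuple[float, float] = (-8.0, 0.0)
    # CADD phred, truncated normal on [0, inf).
    cadd_mu_pathogenic: float = 26.0
    cadd_sd_pathogenic: float = 4.0
    cadd_mu_benign: float = 14.0
    cadd_sd_benign: float = 9.0
    # Reference population size for Hardy–Weinberg homozygote draws.
    population_size: int = 800_000

    def __post_init__(self) -> None:
        probs = (
            self.p_truth_pathogenic,
            self.p_labeled_pathogenic,
            self.p_labeled_benign,
            self.p_vus,
            self.label_error_rate,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if min(self.a_p, self.b_p, self.a_b, self.b_b) <= 0:
            raise ValueError("Beta parameters must be positive")
        if min(self.af_sd_pathogenic, self.af_sd_benign,
               self.cadd_sd_pathogenic, self.cadd_sd_benign) <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n_genes < 1 or self.variants_per_gene < 1:
            raise ValueError("cohort dimensions must be >= 1")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if abs(sum(self.star_probs) - 1.0) > 1e-9 or len(self.star_probs) != 5:
            raise ValueError("star_probs must be 5 probabilities summing to 1")
        if self.af_bounds[0] >= self.af_bounds[1] or self.af_bounds[1] > 0.0:
            raise ValueError("af_bounds must be an increasing pair with upper bound <= 0")


@dataclass(frozen=True)
class SyntheticCohort:
    """File paths of a generated cohort plus its per-variant truth table."""

    predictor_path: Path
    clinical_path: Path
    population_path: Path
    truth: pd.DataFrame = field(compare=False)


_AA = sorted(CANONICAL_AA)


def _truncnorm(mu: float, sd: float, lo: float, hi: float):
    return stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)


def generate_frames(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (predictor, clinical, population, truth) DataFrames.

    Deterministic given ``cfg.seed``; all randomness flows through one
    ``numpy.random.Generator``. Keys are unique by construction (sequential
    residue positions within each synthetic gene).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes * cfg.variants_per_gene

    genes = np.repeat(
        [f"GENE{i + 1:03d}" for i in range(cfg.n_genes)], cfg.variants_per_gene
    )
    positions = np.tile(np.arange(1, cfg.variants_per_gene + 1), cfg.n_genes)
    ref_idx = rng.integers(0, 20, size=n)
    alt_idx = (ref_idx + rng.integers(1, 20, size=n)) % 20  # guarantees ref != alt
    aa = np.array(_AA)
    protein_changes = np.array([
        f"p.{_ONE_TO_THREE[r]}{p}{_ONE_TO_THREE[a]}"
        for r, p, a in zip(aa[ref_idx], positions, aa[alt_idx])
    ])

    is_path = rng.random(n) < cfg.p_truth_pathogenic

    scores = np.where(
        is_path,
        rng.beta(cfg.a_p, cfg.b_p, size=n),
        rng.beta(cfg.a_b, cfg.b_b, size=n),
    )

    lo, hi = cfg.af_bounds
    log_af = np.where(
        is_path,
        _truncnorm(cfg.af_mu_pathogenic, cfg.af_sd_pathogenic, lo, hi).rvs(n, random_state=rng),
        _truncnorm(cfg.af_mu_benign, cfg.af_sd_benign, lo, hi).rvs(n, random_state=rng),
    )
    af = 10.0 ** log_af
    cadd = np.where(
        is_path,
        _truncnorm(cfg.cadd_mu_pathogenic, cfg.cadd_sd_pathogenic, 0.0, np.inf).rvs(
            n, random_state=rng),
        _truncnorm(cfg.cadd_mu_benign, cfg.cadd_sd_benign, 0.0, np.inf).rvs(
            n, random_state=rng),
    )
    homozygotes = rng.binomial(cfg.population_size, af**2)

    # Annotation model: definitive label with class-conditional probability,
    # flipped with the label-error rate; a further slice labelled VUS.
    u = rng.random(n)
    p_def = np.where(is_path, cfg.p_labeled_pathogenic, cfg.p_labeled_benign)
    has_definitive = u < p_def
    is_vus = (~has_definitive) & (u < p_def + cfg.p_vus)
    flipped = rng.random(n) < cfg.label_error_rate
    label_path = np.where(flipped, ~is_path, is_path)
    pick = rng.integers(0, 2, size=n)
    raw_labels = np.where(
        label_path,
        np.where(pick == 0, "Pathogenic", "Likely pathogenic"),
        np.where(pick == 0, "Benign", "Likely benign"),
    )
    raw_labels = np.where(is_vus, "Uncertain significance", raw_labels)
    stars = rng.choice(5, size=n, p=cfg.star_probs)

    predictor = pd.DataFrame({
        "gene": genes,
        "protein_variant": protein_changes,
        "am_pathogenicity": scores,
    })
    labelled = has_definitive | is_vus
    clinical = pd.DataFrame({
        "gene": genes[labelled],
        "protein_change": protein_changes[labelled],
        "clinical_significance": raw_labels[labelled],
        "review_stars": stars[labelled],
    })
    population = pd.DataFrame({
        "gene": genes,
        "protein_change": protein_changes,
        "allele_frequency": af,
        "homozygote_count": homozygotes,
        "cadd_phred": cadd,
    })
    truth = pd.DataFrame({
        "gene": genes,
        "protein_change": protein_changes,
        "truth_class": np.where(is_path, "pathogenic", "benign"),
        "score": scores,
        "allele_frequency": af,
        "cadd_phred": cadd,
        "homozygote_count": homozygotes,
        "has_definitive_label": has_definitive,
        "raw_label": np.where(labelled, raw_labels, ""),
        "review_stars": np.where(labelled, stars, -1),
    })
    return predictor, clinical, population, truth


def generate_cohort(cfg: SyntheticConfig, out_dir: str | Path) -> SyntheticCohort:
    """Generate a cohort and write the three input TSVs plus the truth TSV.

    Output is byte-identical for identical configs (same seed included).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    predictor, clinical, population, truth = generate_frames(cfg)
    paths = SyntheticCohort(
        predictor_path=out / "predictor.tsv",
        clinical_path=out / "clinical.tsv",
        population_path=out / "population.tsv",
        truth=truth,
    )
    predictor.to_csv(paths.predictor_path, sep="\t", index=False)
    clinical.to_csv(paths.clinical_path, sep="\t", index=False)
    population.to_csv(paths.population_path, sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return paths


def panel_genes(cfg: SyntheticConfig) -> list[str]:
    return [f"GENE{i + 1:03d}" for i in range(cfg.n_genes)]


@dataclass(frozen=True)
class ExpectedMetrics:
    sensitivity: float
    specificity: float
    fdr: float


def expected_metrics(
    cfg: SyntheticConfig, classifier: ClassifierConfig | None = None
) -> ExpectedMetrics:
    """Closed-form expected sensitivity/specificity/FDR under the EXCLUDE policy.

    Works from the class-conditional Beta CDFs, mixing in the label-error
    rate: a clinically-pathogenic-labelled variant is truth-pathogenic with
    probability proportional to p_truth * p_labeled_p * (1 - e) and
    truth-benign with probability proportional to (1 - p_truth) *
    p_labeled_b * e; scores are drawn from the corresponding mixture.
    """
    classifier = classifier or ClassifierConfig()
    t_lo, t_hi = classifier.benign_max, classifier.pathogenic_min
    fp_cdf = stats.beta(cfg.a_p, cfg.b_p).cdf
    fb_cdf = stats.beta(cfg.a_b, cfg.b_b).cdf

    e = cfg.label_error_rate
    pt = cfg.p_truth_pathogenic
    w_lab_p_from_p = pt * cfg.p_labeled_pathogenic * (1 - e)
    w_lab_p_from_b = (1 - pt) * cfg.p_labeled_benign * e
    w_lab_b_from_b = (1 - pt) * cfg.p_labeled_benign * (1 - e)
    w_lab_b_from_p = pt * cfg.p_labeled_pathogenic * e

    w_p = w_lab_p_from_p + w_lab_p_from_b
    w_b = w_lab_b_from_b + w_lab_b_from_p
    if w_p == 0 or w_b == 0:
        raise ValueError("expected_metrics requires both label classes reachable")

    def mix_cdf(x: float, f_path_weight: float, total: float) -> float:
        frac_p = f_path_weight / total
        return frac_p * fp_cdf(x) + (1 - frac_p) * fb_cdf(x)

    def f_lab_p(x: float) -> float:
        return mix_cdf(x, w_lab_p_from_p, w_p)

    def f_lab_b(x: float) -> float:
        return mix_cdf(x, w_lab_b_from_p, w_b)

    sens = (1 - f_lab_p(t_hi)) / (1 - (f_lab_p(t_hi) - f_lab_p(t_lo)))
    spec = f_lab_b(t_lo) / (1 - (f_lab_b(t_hi) - f_lab_b(t_lo)))
    tp_mass = w_p * (1 - f_lab_p(t_hi))
    fp_mass = w_b * (1 - f_lab_b(t_hi))
    fdr = fp_mass / (fp_mass + tp_mass)
    return ExpectedMetrics(sensitivity=float(sens), specificity=float(spec), fdr=float(fdr))


def expected_mean_homozygotes(cfg: SyntheticConfig) -> float:
    """E[homozygote count per variant] = N * E[AF^2] under the AF mixture.

    E[AF^2] = E[10^(2L)] with L the class-conditional truncated normal on
    log10 AF, computed by numerical integration and mixed over truth classes.
    """
    lo, hi = cfg.af_bounds

    def second_moment(mu: float, sd: float) -> float:
        dist = _truncnorm(mu, sd, lo, hi)
        val, _ = integrate.quad(lambda x: dist.pdf(x) * 10.0 ** (2 * x), lo, hi)
        return val

    m = (
        cfg.p_truth_pathogenic * second_moment(cfg.af_mu_pathogenic, cfg.af_sd_pathogenic)
        + (1 - cfg.p_truth_pathogenic) * second_moment(cfg.af_mu_benign, cfg.af_sd_benign)
    )
    return cfg.population_size * m


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Convenience: the same generating conditions under a different seed."""
    return replace(cfg, seed=seed)
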