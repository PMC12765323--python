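# Methods

## Scope and data model

The package benchmarks a precomputed missense pathogenicity score set
against clinical assertions for a gene panel, then uses population metrics
to interrogate the discordant calls. Three tables feed the analysis, joined
on a protein-level key (uppercase gene symbol + amino-acid substitution):
predictor scores, clinical labels with review stars, and population metrics
(allele frequency, homozygote count, CADD phred). The cohort is the inner
join of predictor and population records: population presence is the
inclusion criterion, so every cohort member has allele frequency > 0 (an
assertion, not an assumption — ultrarare variants absent from the
population reference never enter, and all downstream estimates must be read
within that sampling frame). Clinical labels attach where they match;
absence is a recorded state.

Matching deliberately ignores genomic coordinates even when present. Scores
are published per representative transcript while clinical submissions cite
arbitrary isoforms; the protein change is the shared identity. Residual
transcript-versioning conflicts are handled by an explicit override map
(clinical key → predictor key), the mechanical equivalent of manual
reconciliation, and every key is accounted for in a match report. Within
one source, duplicate keys keep the first record and log the rest.

## Classification and eligibility

Scores map to a three-way call with exclusive bounds: benign iff
`s < benign_max` (default 0.34), pathogenic iff `s > pathogenic_min`
(default 0.564), ambiguous otherwise. The published operating points are
stated as three-decimal intervals, which leaves the gap (0.333, 0.334)
undefined; the continuous rule assigns every score and reproduces all nine
reference-hypomorph classifications (0.343 → ambiguous, 0.366 → ambiguous,
0.326 → benign), which is the validation we rely on.

Clinical labels collapse case-insensitively: {pathogenic, likely
pathogenic} → pathogenic, {benign, likely benign} → benign; composite
labels ("Pathogenic/Likely pathogenic") collapse when all parts agree.
Everything else — VUS, conflicting interpretations, unrecognized labels,
or fewer than `min_stars` review stars (default 1) — is ineligible, with
the reason recorded rather than raised: non-definitive annotation is a
normal state of the data.

## Concordance and performance metrics

Each definitive variant gets one of six confusion labels (TP/FP/TN/FN plus
two ambiguous buckets, kept separate per clinical side). Metrics are
computed under two policies: EXCLUDE drops ambiguous predictions from
denominators (primary analysis — the ambiguous band is a declared
low-confidence zone, and forcing it into a binary call would manufacture
errors); AS_ERROR folds ambiguous-on-pathogenic into FN and
ambiguous-on-benign into FP (sensitivity analysis). EXCLUDE can only look
better than AS_ERROR, which is itself a property test.

Binomial proportions carry Wilson score intervals. The interval family was
chosen because it uniquely reproduces the published per-gene intervals used
as regression anchors (e.g. 217/297 → 67.7–77.8; 22/22 lower bound 85.1;
1/1 lower bound 20.7); Wald intervals collapse at the boundary counts that
panel data are full of. The implementation is the closed form (tested to
1e-12 against an independent re-implementation and against statsmodels);
bounds at k = 0 and k = n are returned as exact 0 and 1. A zero denominator
yields an explicit undefined metric with a reason — never NaN — because
per-gene tables legitimately have empty sides (a gene with no
benign-labelled variants has no specificity).

Panel summaries: micro FDR pools FP and TP across genes; macro
sensitivity/specificity average defined per-gene values. Two macro
conventions are provided because they genuinely differ: averaging over all
genes with a defined denominator, or additionally dropping genes with
TP = 0 from macro sensitivity (a single gene with 0/3 sensitivity moves a
20-gene average by ~4 points; the reference top-20 summary matches the
drop-zero-TP convention, 83.2% vs 79.1%). The choice is an explicit enum,
default defined-only.

AUROC uses the midrank-corrected rank statistic (scores have 3-decimal
granularity, so ties are routine) and is property-tested against exhaustive
pair counting; AUPRC is step-wise average precision. Both are delegated to
scikit-learn; the brute-force pair-counting oracle lives only in tests.

Report percentages round half-up. One published figure (FDR under
AS_ERROR) appears truncated rather than rounded (exact 18.96% printed as
18.9); the validation compares at printed precision there instead of
asserting our rounding.

## Discrimination

Welch's unequal-variance t-test compares log10 allele frequency and CADD
between TP and FP and between TN and FN — four comparisons,
Bonferroni-corrected (default threshold 0.05/4 = 1.25e-2), two-sided (the
null is "no difference", not a direction). AF is tested on the log10 scale
(frequencies span five orders of magnitude; the cohort invariant AF > 0
makes a pseudo-count unnecessary) with natural-scale group means reported
alongside; CADD is already phred-scaled and compared untransformed. The
Welch–Satterthwaite df is not rounded. Groups under two members make a
comparison not-computable rather than an error. The test statistic is
computed by scipy; an independently coded textbook-formula oracle checks
t, df, and p to 1e-10 in the tests, and a 1000-replicate null simulation
checks the Bonferroni procedure's per-comparison type-I error against
alpha/4 within binomial error.

Homozygote rates are simple shares of variants with ≥ 1 reported
homozygote per confusion group, undefined for empty groups and invariant
under row order.

## Suspicion rules and hypomorph profiles

The flagger encodes directional rules with deliberate asymmetry: suspected
false negative requires the conjunction rare AND high-CADD AND
homozygote-free (all of the pathogenic-like profile), suspected false
positive the disjunction common OR low-CADD OR any homozygote (one
benign-like signal suffices to doubt a pathogenic call). Ambiguous
predictions are never flagged.

The thresholds are operating points, not published constants, and are
prominently configurable. Defaults: AF ≤ 1e-4 counts as rare (the scale of
concordant-pathogenic allele frequencies, order 1e-5), AF ≥ 1e-3 as common
(the scale separating concordant-benign variants), CADD ≥ 20 as damaging
and ≤ 15 as tolerated (bracketing the conventional phred-20 mark between
observed discordant-benign means ~24.6 and concordant-benign means ~13.9),
and zero homozygotes for the false-negative rule. Tightening the
false-negative thresholds can only shrink the flag set (a tested
monotonicity). A documented consequence of the homozygote disjunct: a
genuinely pathogenic but hypomorphic variant with reported homozygotes
trips the false-positive rule — which is exactly why hypomorphs get their
own mechanism.

A hypomorph profile is a per-metric min/median/max envelope over a
reference set (even-count medians average the two central order
statistics); queries are checked with inclusive bounds ("in the range"
includes the endpoints), per metric and overall. Both the full-envelope
mode and a named-comparator mode (a single-reference profile collapses to a
point) are available, since "similar to known hypomorphs" can mean either.

## Synthetic cohorts and expectations

The generator draws a truth class per variant (default P(pathogenic) =
0.2), then everything else class-conditionally, through a single seeded
`numpy` Generator — no global state, byte-identical output per seed.

* **Scores**: Beta distributions. Defaults Beta(0.81, 0.35) for pathogenic
  and Beta(0.18, 1.41) for benign truth were fitted once so that the
  three-way call reproduces panel-scale class shares (pathogenic truth:
  ~69.7% called pathogenic, 18.1% benign, 12.2% ambiguous; benign truth:
  ~87.8% / 5.5% / 6.6%), implying expected sensitivity ≈ 0.79 and
  specificity ≈ 0.94 under EXCLUDE.
* **Annotation**: definitive-label probability 0.35 for pathogenic truth
  and 0.12 for benign truth — clinical databases annotate suspected disease
  alleles far more densely than background variation, and these rates give
  a labelled subset whose pathogenic:benign balance (~43:57) matches
  panel-scale benchmarks; a further 8% get a VUS label to exercise
  ineligibility. The label-error rate defaults to 0 so recovery tests are
  clean; the closed forms handle nonzero error by mixture.
* **Population metrics**: log10 AF ~ truncated Normal on [−8, 0]
  (pathogenic μ = −4.7, σ = 1.0; benign μ = −3.0, σ = 1.5 — matching the
  order-of-magnitude separation between concordant groups), so every
  variant is population-present by construction; CADD ~ Normal truncated
  at 0 (pathogenic 26 ± 4, benign 14 ± 9); homozygotes ~ Binomial(N, AF²)
  with N = 800 000 reference individuals (Hardy–Weinberg).
* **Default size**: 107 genes × 1200 variants ≈ 128k, the scale of a full
  panel score release; tests and analysis scripts use smaller sizes through
  the same contract (the recovery check uses 50 genes × 1000 = 50 000,
  enough for ~8k labelled variants and tight Monte-Carlo error).

What the generator does **not** emulate: linkage and haplotype structure,
per-population AF stratification, realistic gene lengths or mutational
spectra, submitter-correlated label errors, and the structured (disordered
region) failure mode that makes real hypomorphs hard. Passing recovery
tests therefore demonstrate that the pipeline measures what it claims on
data satisfying its own assumptions — not that the predictor performs any
particular way on real variants.

`expected_metrics` gives closed-form EXCLUDE-policy sensitivity/
specificity/FDR from the Beta CDFs (mixed over the label-error rate), e.g.
sensitivity = (1 − F_p(0.564)) / (1 − [F_p(0.564) − F_p(0.34)]).
`expected_mean_homozygotes` integrates N·E[10^(2L)] over the truncated
normal numerically. Pipeline estimates are required to land within 3
binomial standard errors of these at n = 50 000.

## Numerical conventions and degenerate inputs

* Percent reporting rounds half-up (one decimal; two for homozygote rates).
* Equal-mean zero-variance Welch inputs raise (t undefined); zero-variance
  unequal-mean inputs pass through scipy's ±inf.
* Empty cohort (no predictor ∩ population overlap) is a distinct error; a
  cohort with nothing clinically evaluable is a successful run with
  undefined metrics.
* Selenocysteine/pyrrolysine substitutions are rejected as outside the
  20-letter substitution space; stop/frameshift/indel/synonymous changes
  raise a distinct not-missense error so callers can filter rather than
  fail.
* Funnel counts (panel filter, population join, label eligibility,
  ambiguous exclusion) are logged and duplicated into the summary JSON so
  every input variant is accounted for.

## Known limitations

Concordance is measured against clinical-database labels, a moving and
heterogeneous reference, not biological truth; the published per-gene
counts embedded for validation inherit that caveat. The matcher handles
substitutions only (no delins/intronic/UTR grammar, no liftover). The
flagger's thresholds are panel-calibrated defaults, not transferable
constants. ROC/PR on heavily imbalanced labelled subsets should be read
with the usual prevalence caveats.
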