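# Methods

## Model and assumptions

The package treats vaccine immunogenicity as a property of the *combination*
of a person's six HLA class I alleles, not of any single allele. The unit of
prediction is the epitope–genotype pair: a 9-mer window of a vaccine antigen
together with the number of distinct autologous alleles predicted to bind
it. The population-level prediction — the in silico immune response rate —
is the fraction of a genotyped model cohort for whom the vaccine contains
enough sufficiently promiscuous epitopes.

Assumptions baked into the model:

- **Binding implies presentability.** A predicted strong binder (percentile
  rank ≤ 2 by default, or IC50 < 150 nM under the affinity policy) is
  treated as a presentable epitope. Proteasomal processing, TAP transport
  and T-cell receptor recognition are not modelled.
- **Distinct-allele counting.** A homozygous allele counts once toward the
  HLA threshold: the same molecule presents the same peptides, so a
  homozygous genotype has 3–5 distinct alleles and can never reach a
  threshold above its distinct-set size. (Whether a homozygous binder
  should count once or twice is genuinely open; distinct-set counting is
  the package's documented choice.)
- **Epitope identity is (peptide, antigen of origin).** A 9-mer repeated
  inside one antigen counts once; the same 9-mer occurring in two antigens
  counts once per antigen, which is what makes the multi-antigen estimators
  well defined.
- **Stratification narrows enrollment only.** An HLA restriction (e.g.
  "A02", "A\*24:02", "A1 or A2") selects which subjects enter the
  denominator; all six alleles of the retained subjects still count toward
  the threshold. This separation — single-allele enrollment versus
  multi-allele response — is the central contrast the model exists to
  probe.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 9 | scan window length (class I epitope length); configurable, longer administered peptides are handled by scanning their 9-mer windows |
| binder_threshold | 2.0 | percentile-rank cutoff for "binds"; the strong-binder convention. The alternative IC50 policy uses < 150 nM |
| hla grid | n ∈ {1..4} | thresholds of the standard battery; n ∈ {5, 6} are computable but flagged out-of-grid because so few epitopes bind ≥ 5 alleles of one person (< 0.3 per subject) that rates built on them are unstable |
| min_epitopes / min_antigens | (1,1), (2,1), (2,2) | the three estimator families |

The binder cutoff inside the in silico trial is an explicit, logged
parameter rather than a hard-wired constant, because reasonable predictors
disagree on it; all results carry the policy they were computed under (the
run manifest records it).

## Binding predictions

The binding contract is pluggable. Precomputed tables (TSV of peptide,
allele, percentile rank, optional IC50) are the primary path; an absent
(peptide, allele) pair means "no prediction" and is treated as a non-binder
(strict users can detect sparsity by comparing table alleles against cohort
alleles). Duplicate rows keep the best (lowest) rank with a warning.

The built-in default scorer is a per-allele position-specific scoring matrix
with an empirical percentile transform: raw score = sum of per-position
weights; rank = 100 × fraction of a sorted background-score sample strictly
greater than the raw score. It is a deliberately simple, fully reproducible
stand-in behind the same contract as an external predictor; it makes no
claim to the accuracy of trained neural predictors, and windows containing
non-standard residues (X) yield no prediction rather than an error.

## The statistics layer

- **Pearson + t.** r by the product-moment formula; p two-sided from
  Student's t with df = n − 2 via t = r√((n−2)/(1−r²)). Degenerate inputs
  (n < 3, zero variance) raise rather than return NaN.
- **Perpendicular trend.** Orthogonal regression (total least squares,
  equal error variance in both axes — the symmetric choice when both the
  measured and the predicted rate are noisy). Closed form on centered
  second moments: b = (s_yy − s_xx + √((s_yy−s_xx)² + 4s_xy²))/(2s_xy);
  s_xy = 0 resolves to horizontal (s_xx ≥ s_yy) or an explicit
  vertical-line result, never an overflow. The 0.95 confidence and
  prediction bands come from a seeded pairs-bootstrap (2000 resamples by
  default): percentile interval of the refitted line at each abscissa;
  prediction bands add a resampled vertical residual. The bootstrap is the
  package's own documented scheme, chosen because no standard closed form
  exists for orthogonal-fit bands.
- **"n−1" chi-squared.** Pearson χ² of the 2×2 responders table scaled by
  (N−1)/N, no continuity correction, p from χ²(1) — the recommended test
  for two independent proportions at trial-sized samples. A zero margin
  (both rates 0, or both 1) is a perfect match by convention (p = 1).
  Pairwise p-values are descriptive; no multiple-testing correction is
  applied, matching how such match-fractions are reported.
- **ROC/AUC.** Label = measured rate ≥ success threshold; score = predicted
  rate; cutoffs sweep the distinct scores with ties grouped into a single
  vertex; AUC by trapezoid. This construction is algebraically identical to
  the tie-corrected rank-sum statistic U/(n₊n₋), which the tests verify.
  The sweep covers thresholds 30–80% to avoid judging the predictor on
  hopelessly imbalanced labellings; degenerate thresholds are skipped.
- **Group location.** Both a rank test (Mann–Whitney, normal approximation
  with tie correction, no continuity correction) and Welch's t are
  provided; which to use is configuration, not inference.
- **"Within 10%"** means absolute percentage points, inclusive boundary.

## Synthetic data: what it emulates and what it does not

The generators emulate the *structure* of the real inputs, with defaults
chosen once as field-realistic values:

- **Cohorts**: two independent draws per locus from a per-locus frequency
  catalog. The built-in panel holds ten globally common alleles per locus
  with plausible frequencies; it is synthetic, not a copy of any published
  catalog. Loci are unlinked by default (real HLA loci show linkage
  disequilibrium; a haplotype-table mode would be the realism upgrade and
  is out of scope).
- **Binding tables**: each (peptide, allele) pair binds with base
  probability 0.02 — the mass below a rank-2 cutoff, by the definition of a
  percentile — and once a peptide has one binder the remaining alleles bind
  at 0.02 × 2.8. The boost of 2.8 was derived analytically so that
  P(≥ 2 alleles | ≥ 1 allele) ≈ 1 − (1 − 0.056)⁵ ≈ 0.25, the ~25%
  promiscuous-epitope fraction observed in genotyped cohorts.
- **Vaccine suites**: per-vaccine base binder rates drawn from
  (0.005, 0.05) create the realistic cross-vaccine spread in which the
  single-allele rate saturates near 100% while the n = 3 rate spans the
  full range — exactly the regime in which the threshold question is
  interesting.
- **Trials**: measured responders ~ Binomial(cohort, true in silico rate).
  Real trial noise also includes assay heterogeneity, varying positivity
  criteria and prior-treatment effects; none of that is modelled, so
  passing recovery tests show pipeline self-consistency, not clinical
  validity.

All generators are pure functions of (parameters, seed); the run seed fans
out to per-component child seeds via `numpy.random.SeedSequence`, so adding
a generator never perturbs existing streams.

## Numerical and design choices

- Rates are exact integer numerator/denominator pairs; monotonicity
  properties (non-increasing in n, in breadth) hold exactly, not to
  tolerance.
- An empty post-stratification stratum returns `None` from
  `stratify_population` (a population type cannot be empty); the trial
  layer converts it into an explicit no-denominator error.
- Allele nomenclature accepts exactly four spellings (`A*02:01`, `A02:01`,
  `A*0201`/`A0201`, group-level `A02`/`A2`); anything else is an error, not
  a guess. Three-digit concatenations (`A201`) are ambiguous and rejected.
- Per-peptide mode exists in two variants, because trials report per-peptide
  immunogenicity against the administered peptide: mode "antigen" treats
  each antigen record as one administered peptide (any passing window
  counts), mode "window" rates each distinct 9-mer separately.
- In the threshold-recovery experiment a constant predictor column
  (typically the saturated n = 1 row) is assigned r = 0 — it carries no
  linear information — while `pearson_with_p` itself raises on zero
  variance.
- Coordinates are 0-based half-open internally, 1-based inclusive in
  human-readable outputs.

## Problem sizes

The test suite and acceptance script run at desk scale by design: oracle
equivalence on 100 random cohorts of ≤ 20 subjects; monotonicity on 50;
threshold recovery on a 150-subject population × 40 vaccines × 10 seeds
with cohorts of 200–300; frequency recovery at 5000 subjects; coverage on a
433-subject sample. These sizes give stable answers for every claim tested
while keeping a full run in well under a minute.

## Known limitations

- The default scorer is not a validated binding predictor; quantitative
  agreement with any published trial analysis requires plugging in real
  prediction tables.
- No HLA class II, no TCR-recognition modelling, no processing/transport
  steps.
- The synthetic catalog covers common alleles only; rare-allele coverage
  questions need a real frequency catalog supplied as CSV.
- Trial covariates (vaccine formulation, dosing, prior treatment, assay
  type) are outside the model.
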