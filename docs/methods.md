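# Methods

## Model

The screening score is a tree-augmented naive Bayes (TAN) classifier over six
categorical predictors: sex (male/female), age band (<40, 40–54, 55–69, ≥70
years), increased neck circumference (yes/no), craniofacial abnormalities
(yes/no), witnessed apneas (yes/no), and nocturia (yes/no). The class is the
PSG outcome — OSA defined as AHI ≥ 5 events/h (the comparison is closed: an
AHI of exactly 5 is positive; AHI ≥ 15 marks moderate/severe disease).

A TAN assumes each predictor depends on the class and on at most one other
predictor, the predictor–predictor edges forming a tree. This captures
first-order within-class dependence (e.g. nocturia rises with age regardless
of OSA) at a cost that remains linear in the number of features, and keeps
exact inference trivial.

### Structure learning

Chow–Liu adapted to the class-conditional case: for every feature pair,
estimate the conditional mutual information I(X; Y | C) in bits from the
3-way contingency counts, then take the maximum-weight spanning tree of the
complete feature graph. Choices that the TAN literature leaves open, fixed
here:

- **CMI estimator** — plug-in on additively smoothed counts, using the same
  smoothing constant as parameter fitting (default α = 1). A variable with a
  single observed level gets CMI 0 (with a warning) rather than a smoothed
  value: smoothing a degenerate margin would manufacture spurious dependence.
- **Determinism** — Kruskal's algorithm with edges sorted by (weight
  descending, lexicographic name pair ascending), so ties never depend on row
  order or hash order. Re-fitting on a permuted cohort gives the identical
  structure.
- **Root** — the lexicographically smallest feature name (`age_band`). The
  root only fixes the CPT parameterization; any rooting of the same
  undirected tree represents the same joint distribution.
- **Missing training values** — available-case analysis: a row contributes to
  every count whose variables it has observed. Deterministic and unbiased
  under missingness that is independent of the missing value given the
  observed ones; EM-style imputation is deliberately out of scope.

### Parameters

Conditional probability tables are additively smoothed relative frequencies,

    P(x | parents) = (n_{x,parents} + α) / (n_{parents} + α·|levels(x)|),

with α = 1 (Laplace) by default, exposed as `TANClassifier(alpha=...)`. A
parent configuration never observed under α = 0 falls back to a uniform
vector. The class prior is smoothed the same way.

### Inference

The score is the exact posterior P(OSA | observed evidence). Missing evidence
is marginalized exactly: the factorized joint is summed over all level
combinations of the missing features (at most 4·2⁵ = 128 terms per class for
the six screening variables). Log-space accumulation with log-sum-exp guards
against underflow; fully observed rows take a vectorized fast path. With no
evidence at all the posterior equals the class prior, as it must.

## Validation pipeline

Mirrors standard external validation of a clinical prediction rule:

- **Descriptive comparison** (OSA vs non-OSA): categorical variables as n (%)
  with the chi-squared test, switching to Fisher's exact test when any
  expected 2×2 cell is below 5; continuous variables as mean (SD) with
  Welch's t-test when both groups pass Shapiro–Wilk at the 5% level,
  otherwise median (IQR) with Mann–Whitney. The gate is configurable
  (`continuous_test="auto"|"t"|"mw"`). P-values are reported unadjusted, as
  is conventional for a descriptive cohort table.
- **ROC/AUC** per stratum (all, PSG I, PSG III) and outcome threshold (5 and
  15 events/h). Operating points are taken at every distinct score with the
  strict `score > cutoff` positivity rule; the trapezoidal AUC then equals
  the Mann–Whitney statistic with half credit for ties. The AUC confidence
  interval uses the DeLong variance (Hanley–McNeil available) with a Wald
  interval truncated to [0, 1]; two strata on disjoint subjects are compared
  with an unpaired z-test on summed DeLong variances.
- **Cutoff** — selected once, on the full cohort at the diagnostic threshold,
  as the operating point maximizing specificity among those with sensitivity
  ≥ 0.95 (ties resolve to the larger cutoff), then reused unchanged for every
  stratum and the moderate/severe threshold. The all-positive point
  (sensitivity 1) always qualifies, so selection fails only for floors above
  1; the "refer everyone" fallback is the honest degenerate answer for a
  score with no usable signal.
- **Metric battery** with 95% CIs: Wilson score intervals for proportions
  (Clopper–Pearson optional), the Katz log method for likelihood ratios, the
  Woolf log method for the diagnostic odds ratio. Post-test odds = pre-test
  odds × LR, with the CI scaled from the LR interval (prevalence treated as
  fixed). The F-score CI is a binomial approximation on its pseudo-counts and
  is flagged as such. Zero cells yield ∞/0 with a flag by default; a
  Haldane–Anscombe +0.5 correction is available. Subjects with missing
  predictors are scored through marginalized inference, never dropped;
  subjects with missing AHI cannot be labelled and are excluded and counted.

Published accuracy tables can be inverted: `reconstruct_confusion(n, n_pos,
sens, spec)` recovers the integer 2×2 cells (rounding half away from zero),
and `reconstruct_report` composes it with the battery. Some published ratio
metrics (DORs, one LR+) are derivable only from the *rounded* printed rates
rather than the integer cells; `ratio_metrics_from_rates` implements that
path explicitly. Report rendering rounds half away from zero to the
conventional printed precision (percentages to 1 dp, ratios to 2 dp).

## Synthetic cohorts

The generator emulates the reference validation cohort: PSG stratum
(P(III) = 143/216), OSA status from the stratum prevalence (0.90 in PSG III,
0.66 in PSG I, implying ≈ 0.82 marginally), severity among cases
(0.44/0.32/0.24 mild/moderate/severe), then each predictor from its
class-conditional distribution (e.g. male 107/177 vs 12/39; age from a
truncated normal ≥ 18 with mean ± SD 59 ± 12 vs 48 ± 11). AHI within a
severity band: uniform on [0,5), [5,15), [15,30) and 30 + Exponential(15)
for severe — only the band membership matters for label-level validation, so
any within-band law suffices; values are floored to 1 dp so band membership
survives formatting. Neck circumference is log-normal moment-matched to the
published medians/IQRs (41 [38–44] vs 36 [33–39] cm). Descriptive covariates
(BMI, Epworth score, snoring, comorbidities) follow the published group
frequencies. One `numpy` Generator stream per cohort, fully determined by the
seed; identical seeds give byte-identical CSVs.

**What the generator does not emulate:** predictors are drawn independently
given the class, so the real cohort's within-class joint dependencies (not
published) are absent, and the real study's AUC is not a generator target.
Tests passing on these cohorts demonstrate the correctness of the machinery,
not the clinical performance of the score. When within-class dependence is
needed — parameter-recovery studies — `generate_from_model` samples exactly
(ancestral order) from a fitted or hand-specified TAN instead.

`reference_tan_model()` is the hand-specified ground truth used in recovery
studies. It is deliberately well conditioned: balanced class prior,
near-uniform root distribution, strong parent effects (0.7 vs 0.3) on every
edge so each edge is identifiable, and extreme probabilities in the cells
conditioned on the 4-level root, whose effective counts are smallest. At
n = 50,000 the smallest cells retain effective counts above ~6,000, putting
3–4 binomial standard errors inside the 0.02 error budget the recovery study
asserts.

## Encoding conventions

- Age bands are left-closed, right-open — [18,40), [40,55), [55,70),
  [70,∞) — so age 40.0 falls in "40-54" and 70.0 in ">=70"; edges are
  configurable.
- "Increased" neck circumference defaults to ≥ 40 cm (the reference cohort
  median), optionally sex-specific; a precomputed `nc_increased` column
  overrides the rule. Obesity (BMI ≥ 30) and increased Epworth score (≥ 11)
  follow standard clinical conventions and feed only the descriptive table,
  never the classifier.
- Missing values are explicit (`None` / empty CSV cell) end to end; no module
  imputes.

## Numerical and degenerate-input conventions

- Probability arithmetic in log space; CPT entries clipped at 1e-300 before
  taking logs so an α = 0 zero stays effectively −∞ without raising.
- Posterior rows sum to 1 within 1e-12; model JSON serialization uses
  shortest-round-trip floats, so save/load reproduces predictions
  bit-identically.
- Rounding for printed tables and confusion-table reconstruction is half away
  from zero (not banker's rounding).
- Empty inputs, single-class inputs, unlabelable subjects (missing AHI) and
  schema-version mismatches raise informative errors rather than degrading
  silently; a missing AHI is never coerced to "no OSA".

## Problem sizes used in the shipped studies

Recovery: 20 replicates of n = 50,000 from the reference TAN. Pipeline AUC
band: 20 model-sampled cohorts of n = 5,000 (the band [0.70, 0.95] is a
sanity corridor, not a point estimate). Generator calibration: n = 100,000
with 3-standard-error tolerances. Type-I error of the AUC comparison: 1,000
replicate pairs with 100 subjects per class.

## Limitations

- The published model's conditional probability tables are not public; this
  package learns its own parameters from data and cannot reproduce the
  original study's score values or its exact cutoff.
- The independence-given-class generator cannot reproduce the real cohort's
  AUC; validation numbers on synthetic cohorts characterize the pipeline, not
  the instrument.
- Available-case learning is biased when missingness depends on the
  unobserved values; the package neither detects nor corrects that.
- The AUC comparison assumes disjoint samples (it is the unpaired variant);
  comparing overlapping cohorts with it is the caller's error.
- Only class-plus-tree topologies are supported — this is not a general
  Bayesian-network engine, and continuous predictors must be discretized by
  the encoding layer.
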