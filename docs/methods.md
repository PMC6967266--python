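# Methods

## Problem setting and model

The package targets biomarker discovery across many independently
profiled tumor/non-tumor expression cohorts. Because absolute intensities
are not comparable across platforms, inference is built from
*within-cohort* statistics only (per-cohort tests, per-cohort thresholds)
and combined by vote counting rather than by pooling values. The final
product is (i) a set of core genes reproducibly differential across
cohorts, (ii) a small panel of those genes with per-gene decision
thresholds and multi-gene classifiers, and (iii) survival stratification
evidence for the panel genes.

## Preprocessing

- **Probe aggregation.** Multiple probes mapping to one gene symbol are
  averaged (arithmetic mean of log-scale rows); unmapped probes are
  dropped. Symbols match case-sensitively with no alias resolution —
  cross-platform symbol harmonization is the caller's responsibility.
- **log2 transform.** Linear-scale input (FPKM-like) is transformed as
  `log2(x + 1)`. The pseudocount of 1 is fixed: it is zero-safe, maps 0
  to 0, and is the conventional choice.
- **Quantile normalization** is applied per cohort, after aggregation.
  The reference distribution is the row-wise mean of column-sorted
  values; tied values within a column receive the mean of the reference
  quantiles their block occupies. On untied (continuous) data the map is
  exactly idempotent; with ties a second application can move values by a
  small amount because tie-averaging perturbs the reference — the
  fixed-point property is therefore only guaranteed for untied input.
  A single-sample matrix is returned unchanged with a warning.
- **Ordering choice.** Whether normalization precedes or follows probe
  aggregation is not canonical; the package normalizes after aggregation
  so that the normalized distribution is the one the downstream tests and
  thresholds see.

## Differential expression and consensus

Unpaired cohorts use Welch's unequal-variance *t*-test; cohorts with
pairing metadata use the Wilcoxon signed-rank test on within-pair
differences (exact null for ≤ 25 nonzero pairs, normal approximation with
continuity correction above). Tests are two-sided. Multiplicity is
controlled per cohort by Bonferroni over the genes actually tested in
that cohort — the family is the cohort's own analysis, not a global gene
universe. Zero-variance genes get *p* = 1 and can never be significant,
which keeps NaNs out of the pipeline. Default significance is adjusted
*p* < 0.01.

Consensus tallies count every cohort's direction (significant or not),
so direction counts always sum to the cohort number; significance counts
feed the core-gene filter: a gene is *core* when significant in at least
80% of cohorts, compared on raw counts (22/27 qualifies, 21/27 does not)
so printed-percentage rounding can never flip a call. Consensus
regulation is the direction majority; an exact tie defers to the
direction among significant cohorts. Rows where the overall majority
disagrees with the majority among significant cohorts are flagged
(`DirectionConflict`) rather than silently relabeled. Percentages are
printed to two decimals with half-up rounding.

## Threshold classifiers and metrics

The single-gene classifier is fit by exhaustive search over every
threshold that can change training predictions: midpoints of consecutive
sorted unique expression values plus ±∞ sentinels. The objective is
training accuracy; ties break toward higher MCC and then the lower
threshold, making the fit deterministic. The choice of accuracy as the
objective (with MCC as tie-break) is a design decision; the search is
complete, so the fitted accuracy equals the global maximum over the grid
by construction, and the test suite re-verifies this against an
independent brute-force oracle. A sample exactly at the threshold is not
"above" it: for an up-regulated gene it is called normal. Constant
expression yields a flagged majority-class model.

MCC is 0 by convention when any denominator factor vanishes. AUROC is
computed from the direction-oriented raw expression (negated for
down-regulated genes), never from the binary stump output — a binary
predictor could not exceed its accuracy-implied AUROC, while the raw
expression retains full ranking information.

`reconstruct_confusion` inverts printed sensitivity/specificity
percentages to integer counts (nearest integer, half away from zero),
which lets published performance rows be audited exactly; with class
sizes of a few hundred, the integer solution is unique at two-decimal
precision.

## Panel selection and models

Ranking uses the full training cohort; the shortlist keeps the top 10 by
training performance and re-scores them by stratified 10-fold
cross-validated stump accuracy to keep 5. Backward wrapper elimination
then removes one feature at a time, scoring every leave-one-out subset by
mean 10-fold CV AUROC of a wrapped classifier; the default wrapper model
is logistic regression (fast, convex, deterministic), exposed as a flag.
Every evaluated subset and score is appended to an audit log so the
selection can be replayed.

Grid-search spaces are deliberately small and standard: trees
`n_estimators ∈ {100, 500}`; k-NN `k ∈ {3, 5, 7, 11}`; logistic
`C ∈ {0.01, 0.1, 1, 10}`; RBF-SVC `C ∈ {0.1, 1, 10} × gamma ∈ {scale,
0.01, 0.1}`; Gaussian naive Bayes has no grid. All cross-validation is
stratified with a fixed seed. Features enter the models as raw log2
expression (no rescaling): values live in a narrow, comparable range
after normalization.

External evaluation cuts continuous scores at the model's native decision
threshold — 0.5 on predicted probabilities, 0 on the SVC margin — and
reports the full metric suite plus AUROC with a stratified-bootstrap
(positives and negatives resampled separately) 95% percentile CI, 2,000
resamples by default. Cross-cohort location shifts can degrade
threshold-dependent accuracy while leaving AUROC intact; both are
reported for exactly this reason.

## Survival analysis

Gene expression is dichotomized at the cohort mean over the patients
present in the survival table; strictly greater than the mean is "high",
ties go low. Risk groups are compared by the two-group log-rank test with
Kaplan–Meier estimates per group. Cox proportional-hazards fits use the
Efron tie approximation (lifelines' default, matching the R survival
ecosystem). Univariate fits run per dichotomized gene and per clinical
covariate (age in years; gender coded M=1; stage as a single ordinal 1–4
covariate); the multivariate model includes only variables univariately
significant at *p* < 0.05, and is skipped when fewer than two qualify.
Collinear covariates are rejected up front with the offending pair named;
monotone-likelihood non-convergence is returned as a flagged result with
infinite CI bounds instead of raising. Missing covariate values are
handled complete-case per model with the retained patient/event counts
reported.

## Synthetic data

The generator emulates the multi-cohort study design at the
post-preprocessing log2 stage (it does not model probe physics or
sequencing counts):

- Per-gene baselines `mu_g ~ Uniform(4, 12)`, matching the magnitude
  range of real log2 intensities so learned thresholds are realistic.
- Per-cohort platform shifts `Normal(0, platform_shift_sd)` applied to
  all genes of a cohort (a location batch effect).
- Planted up/down genes add ±`effect_size` to the tumor mean, but only in
  `round(consistency × n_cohorts)` cohorts per gene, drawn
  deterministically from the base seed — this makes the ≥80% consensus
  rule a falsifiable recovery target rather than a tautology.
- Paired cohorts add a per-patient intercept `Normal(0, noise_sd/2)`
  shared between a patient's tumor and normal sample, the structure a
  signed-rank test exploits.
- Survival: event times are exponential with hazard
  `baseline × exp(Σ log_hr × covariate_centered)`; censoring is the
  minimum of an independent exponential whose rate is
  `baseline × censor_rate/(1 − censor_rate)` (≈ the requested censored
  fraction) and an administrative follow-up cap.

Reference conditions used throughout the test suite: 10–12 cohorts of
30 + 30 samples, 1,000 genes, 20 planted (10 up, 10 down) at effect 3,
consistency 0.9, unit noise and platform scatter. Survival recovery uses
n = 500 patients at ~30% censoring. These sizes keep each stage's signal
comparable to a well-powered cohort while making full multi-replicate
runs fast.

All randomness flows from one integer seed via `numpy.random
.SeedSequence`; cohorts are reproducible individually from
`(seed, cohort_index)`, and a ground-truth ledger (planted genes, carrier
cohorts, baselines, shifts, paired cohorts) is emitted beside the data.

What passing on synthetic data does *not* show: robustness to scale (not
just location) batch effects, gene–gene correlation structure, annotation
mismatches across platforms, non-normal expression distributions, or
informative censoring. Results on real cohorts depend on those factors.

## Pipeline and reproducibility

The orchestrator enforces cohort roles: discovery cohorts vote in the
consensus, exactly one training cohort drives ranking/selection/training,
and validation cohorts are not read before the evaluation stage. All
thresholds (alpha 0.01, consensus 0.80, shortlist 10 → 5, panel size 3)
are config defaults and overridable. Report tables are plain TSV; the run
metadata carries a hash of the scientific configuration (output location
excluded) plus the seed, so a rerun with the same config and seed
reproduces every table byte for byte.

## Known limitations

- Vote-counting consensus ignores effect-size magnitude; a random-effects
  meta-analysis would weight cohorts differently.
- The stump objective (accuracy) is sensitive to class imbalance; with
  strongly imbalanced cohorts MCC or balanced accuracy would be a better
  objective.
- Wrapper elimination is greedy; it does not revisit dropped features and
  can tie when subsets saturate CV AUROC at 1.0 (strong effects), in
  which case the elimination order among tied subsets is alphabetical.
- Quantile normalization assumes most genes are non-differential within a
  cohort; it is applied per cohort and cannot remove cross-cohort scale
  differences by construction.
- No proportional-hazards diagnostics, time-varying covariates, or
  competing-risks handling.
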