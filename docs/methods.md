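# Methods

This note documents the statistical procedures implemented in `pyrotier`,
the defaults and why they were chosen, what the synthetic cohort generator
does and does not emulate, and the package's known limitations.

## Cohort model

A cohort is one row per glioblastoma patient treated with radiotherapy
plus concomitant temozolomide: percent methylation at CpGs 76–79 of the
*MGMT* promoter (pyrosequencing readout) and/or their mean, age at
surgery, sex, preoperative ECOG performance status (0–4), extent of
resection (gross-total GTR, near-total NTR, subtotal STR, biopsy), and
overall survival in months from primary surgery with a death indicator
(alive patients censored at last follow-up). Methylation values are
accepted as arbitrary reals in [0, 100] because assay reporting precision
varies by laboratory; a supplied mean is checked against the recomputed
CpG mean with absolute tolerance 0.51 so that externally rounded integer
means still validate, and is recomputed when absent. Validation is total:
every input row is either accepted or appears exactly once in the
rejection summary with a reason code.

## Unsupervised cut-off: normal mixture on log methylation

Mean methylation is floored at `floor_pct` (default 0.5%, guarding
against log(0) on fully unmethylated reads — the choice is conservative
relative to typical assay background and is configurable), natural-log
transformed, and fitted with a two-component normal mixture by EM. The
log base is immaterial as long as it is applied consistently; natural log
is used throughout. EM runs from 10 starts — a median split plus 9 random
perturbations with sub-seeds derived from the user seed — and the best
log-likelihood fit is kept, components sorted by mean; exact likelihood
ties break toward the lower first-component mean. Convergence is a
relative log-likelihood change below 1e-10 (cheap at these data sizes and
removes start-order sensitivity); a component standard deviation below
1e-6 or weight below 1/n aborts the fit as degenerate rather than
returning a spike component.

The cut-off is the solution of π₁N(x; μ₁, σ₁²) = π₂N(x; μ₂, σ₂²) on the
log scale: a quadratic in x for σ₁ ≠ σ₂, linear for σ₁ = σ₂. Only a root
in the open interval (μ₁, μ₂) is accepted — quadratic crossings outside
that interval are tail artifacts where one component dominates the whole
between-means region, and the estimator reports a no-intersection
diagnostic instead. The root is back-transformed with exp; both the raw
percentage and its round-half-up integer are reported, since clinical
thresholds are quoted as integers but the raw value is what downstream
sensitivity analyses need. Two components are fixed by design: the method
presumes bimodality, and model selection over component counts is out of
scope.

## Supervised cut-off: cross-validated AFT threshold search

The survival model is a log-logistic accelerated failure time
regression: log T = x′β + σW with W standard logistic, fitted by censored
maximum likelihood. Events contribute the log density
z − 2·log(1+eᶻ) − log(σt) and censored subjects the log survival
−log(1+eᶻ), z = (log t − x′β)/σ. Optimization is L-BFGS-B over (β, log σ)
with the analytic gradient; log σ keeps the scale positive without
constraints. The default start (intercept at the log median time, all
else 0, σ = 1) converges in all tested settings.

Covariate codings, unstated in the source design and therefore fixed here
as defaults (all switchable): age standardized as (age − 60)/10 so its
coefficient is per decade around a typical glioblastoma age; performance
status as a numeric-ordinal term; resection treatment-coded with GTR as
reference. The model is main-effects only.

Candidate cut-offs are the integers 1–25%. Folds (5, stratified by event
indicator so every training split has events) are formed once per scan
and shared across candidates; for each candidate c the marker is
dichotomized as methylated = value > c — so the selected c reads
"unmethylated ≤ c" — the AFT model is fitted on each training 4/5 and the
held-out 1/5 is scored by Harrell's C of its linear predictor (higher
η = longer predicted survival). The selection score is the mean of the
five fold C values; scoring on pooled out-of-fold predictions is
available as an option. Candidates whose training dichotomy is degenerate
(single class) in any fold are recorded invalid and excluded. Ties break
toward the lowest candidate: a lower "unmethylated" threshold withholds
the methylated label — and hence potentially beneficial chemotherapy —
from fewer patients, the conservative direction. The scan is
deterministic given the fold seed. The final coefficients reported by the
pipeline come from refitting on the full cohort at the selected
threshold.

Harrell's C is computed over comparable pairs: (i, j) with tᵢ < tⱼ and i
dead, or tᵢ = tⱼ with exactly one death (the dead patient counted
earlier). Pairs with both dead at the same time, or neither comparable
under censoring, are excluded; tied predictions count one half. This is
the classic definition; conventions differ across packages, which is why
the implementation is pinned to an exhaustive-pair oracle in the tests.

## Three tiers, overlap, and survival comparison

The rule is lower = supervised cut-off, upper = unsupervised cut-off
(at its rounded integer): unmethylated ≤ lower, methylated ≥ upper,
gray zone strictly between. If lower ≥ upper the gray zone is empty and
the rule collapses to the single threshold at upper, with a logged
notice. The overlap statistic reports, among patients whose mixture
posterior favors the methylated component (> 0.5), the fraction lying
above the supervised cut-off — i.e. how rarely the survival-informed
rule calls a mixture-methylated tumor "truly unmethylated" — plus the
complementary direction, since either reading is clinically meaningful.

Kaplan–Meier estimation uses the product-limit estimator (delegated to
lifelines) with the standard convention that events precede censoring in
the risk set at tied times; the median is the smallest time with
S(t) ≤ 0.5. Fixed-horizon rates beyond the last observed time carry the
last estimate with an explicit extrapolation flag. The two-group log-rank
test is computed in-package from the O/E/V hypergeometric table (the
per-group observed and expected counts are part of the reported result)
and referred to χ²(1). Pairwise tier comparisons are reported unadjusted,
with a Bonferroni option off by default.

## Synthetic cohort generator

The generator emulates the joint structure the analysis assumes, with
defaults calibrated to the summary statistics of the population the
pipeline was designed for:

* n = 451; latent class unmethylated with probability 0.55.
* Latent log-methylation N(0.92, 0.55²) (unmethylated; median ≈ 2.5%)
  or N(3.40, 0.60²) (methylated; median ≈ 30%); each of the four CpG
  values is exp(latent + N(0, 0.15²)) clipped to [0.5, 100]; the mean of
  the four is the classifying marker. These components put ≈ 55% of
  patients at or below 8% mean methylation and are well separated
  (|μ₁ − μ₂| ≈ 2.5 ≥ 2σ), matching the bimodality the mixture step
  presumes.
* Covariates drawn independently from marginals of a typical
  population-based glioblastoma cohort: age N(62, 11²) clipped to
  [18, 82] (median ≈ 62); 64.7% male; performance status probabilities
  (0.257, 0.350, 0.353, 0.031, 0.009); resection probabilities
  (0.359, 0.233, 0.257, 0.151) for GTR/NTR/STR/biopsy. Independence is a
  simplification — only marginals were available to calibrate against.
* Survival: log T = 2.78 + 0.73·methylated − 0.08·(age−60)/10 −
  0.10·PS + β_res + 0.55·W, β_res = (0, −0.05, −0.15, −0.30), W standard
  logistic; uniform administrative censoring on [45, 120] months. These
  values give median overall survival ≈ 12.9 months (unmethylated class)
  vs ≈ 27 months (methylated class) and ≈ 8% of patients censored alive,
  the regime the pipeline targets. b_meth = 0.73 ≈ log(27/13) is the
  class effect implied by those medians.
* An optional `survival_dichotomy_pct` drives survival from the observed
  dichotomy mean_meth > c instead of the latent class — a sharp known
  threshold used by the recovery tests for the supervised scan.

What the generator does **not** emulate: correlation between covariates
(and between covariates and methylation — the real gray zone skews older
and frailer), intratumoral heterogeneity of methylation, per-CpG
systematic offsets, assay rounding, informative censoring, and
cohort-level heterogeneity across hospitals. Tests passing on these
cohorts therefore establish the estimators' correctness and calibration
under the assumed model, not robustness to those real-data features.

## Problem sizes and numerical checks

The test suite exercises each estimator at the scale where its sampling
error is far below the tolerance checked: mixture recovery at n = 5000
over 20 seeds (5% relative error), AFT bias at n = 5000 over 20 seeds
(|bias| < 0.05 per parameter), threshold recovery at n = 2000 over 10
seeds (±2 points around a sharp generative threshold at 10%), log-rank
type-I error over 2000 null simulations of n = 60. The closed-form
intersection is pinned to a 1e-6-step sign-scan oracle (agreement 1e-5),
concordance and the log-rank statistic to exhaustive-enumeration oracles
(exact / 1e-9), and the AFT, mixture and log-rank routines are
additionally cross-checked against lifelines and scikit-learn. The
end-to-end default analysis (n = 451) runs in a few seconds.

## Known limitations

* Two mixture components are fixed; unimodal or trimodal methylation
  distributions are reported as degeneracy/no-intersection errors rather
  than handled.
* No uncertainty is attached to either cut-off (no bootstrap CI) and the
  cross-validated scan is a single repetition by default; a repeats
  option exists for stability studies.
* The AFT reports coefficients, time ratios and approximate standard
  errors but no p-values; the log-logistic family is the only one
  implemented, by design.
* Pairwise log-rank p-values are unadjusted by default, mirroring how
  such three-group comparisons are usually reported.
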