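# pyrotier

Three-tier classification of *MGMT* promoter methylation for glioblastoma
pyrosequencing assays, combining a distribution-based and a
survival-informed cut-off.

## The problem

*MGMT* promoter methylation is the key predictive biomarker for benefit
from alkylating chemotherapy (temozolomide) in IDH-wildtype glioblastoma.
Pyrosequencing assays report a quantitative percent methylation at CpG
sites 76–79 of the *MGMT* promoter, but laboratories disagree on where to
cut the continuous readout into "methylated" and "unmethylated". A single
threshold also hides the clinically awkward middle range in which some
patients may still benefit from treatment.

`pyrotier` implements, as a tested and reusable pipeline, a three-tier
classification built from two independently derived cut-offs:

1. **Unsupervised cut-off.** Mean methylation is strongly bimodal. A
   two-component normal mixture is fitted by EM to the logarithmized
   values,

   f(x) = π₁ N(x; μ₁, σ₁²) + π₂ N(x; μ₂, σ₂²),  x = log(% methylation),

   and the cut-off is the intersection point of the two *weighted*
   component densities, π₁ N(x; μ₁, σ₁²) = π₂ N(x; μ₂, σ₂²) — a quadratic
   (linear when σ₁ = σ₂) solved in closed form and back-transformed to the
   percent scale. Values at or above it are called **methylated**.

2. **Supervised cut-off.** For each candidate threshold c ∈ {1, …, 25}%,
   methylation is dichotomized at c and a log-logistic accelerated failure
   time (AFT) model

   log T = β₀ + β_meth·1{meth > c} + β_age·(age−60)/10 + β_ps·PS +
   β_res[resection] + σW,  W ∼ standard logistic,

   is refitted under 5-fold cross-validation; candidates are scored by the
   out-of-fold Harrell concordance index and the maximizer is selected.
   Values at or below it are called **truly unmethylated**.

The interval strictly between the two cut-offs is the **gray zone**. The
pipeline finishes with Kaplan–Meier curves, per-tier median overall
survival, fixed-horizon survival rates and pairwise log-rank tests, and a
comparison of the CpG mean against each individual CpG as the classifying
marker.

Because the registry data behind this design are not publicly deposited,
the package ships a seeded synthetic cohort generator
(`pyrotier.simulate`) whose defaults emulate that population: 451
patients, bimodal log-normal methylation (~55% at or below 8%), Table-like
covariate marginals, log-logistic survival with median overall survival
near 13 months (unmethylated) vs 27 months (methylated), and ~8% of
patients censored alive.

## Worked example

```python
import pyrotier as pt

cohort, truth = pt.simulate_cohort(pt.default_config(seed=1))

mix = pt.MethylationMixture(cohort.df.mean_meth.to_numpy()).fit(seed=2)
print(mix.summary())
```

```
Two-component normal mixture on log percent methylation
  n = 451, log-likelihood = -691.708, EM iterations = 35, converged = True
  component      weight     mu(log)   sd(log)   median(%)
  unmethylated    0.581      0.897     0.588       2.45
  methylated      0.419      3.416     0.610      30.45
  intersection cut-off: 8.894% (reported as 9%)
```

The low component sits near 2.5% methylation (assay background in
unmethylated tumors), the high component near 30%; their weighted
densities cross at 8.9%, so ≥ 9% is the unsupervised "methylated" call for
this cohort.

```python
aft = pt.LogLogisticAFT.from_cohort(cohort, cutoff=8).fit()
print(aft.summary())
```

```
Log-logistic AFT model (censored maximum likelihood)
  n = 451, events = 432, log-likelihood = -1750.777, converged = True
  scale sigma = 0.4886
  term                  coef      time ratio
  intercept              2.6607       14.3062
  methylated             0.7741        2.1687
  age_std               -0.1044        0.9009
  preop_ps              -0.0584        0.9433
  resection_NTR         -0.1127        0.8934
  resection_STR         -0.0570        0.9446
  resection_biopsy      -0.1352        0.8735
```

The time ratio 2.17 on `methylated` says patients above the 8% cut-off
live, other factors equal, about twice as long — the direct AFT reading of
the methylation benefit under temozolomide-based treatment.

The whole analysis in one call (or `pyrotier run-all --seed 1
--output-dir demo` from the shell):

```python
report = pt.run_pipeline(pt.default_config(seed=1), seed=1)
print(report.rule.description)
print(report.tiers.counts)
```

```
unmethylated <= 8%, gray zone > 8 to < 9%, methylated >= 9%
{'unmethylated': 260, 'gray_zone': 2, 'methylated': 189}
```

On this synthetic draw the supervised scan selects ≤ 8% and the mixture
intersection ≥ 9%, leaving a narrow gray zone; 260 of 451 patients (58%)
are called truly unmethylated. The report also carries per-tier median
survival (11.6 vs 25.2 months for unmethylated vs methylated here),
12/24/60-month survival rates, pairwise log-rank tests and the per-CpG
concordance comparison, serialized as schema-validated JSON.

## Layout

| module | contents |
|---|---|
| `pyrotier.cohort` | cohort CSV schema, validation, summaries |
| `pyrotier.simulate` | seeded synthetic cohort generator + ground truth |
| `pyrotier.mixture` | EM mixture fit, intersection cut-off |
| `pyrotier.aft` | log-logistic AFT MLE, Harrell's C |
| `pyrotier.threshold` | cross-validated threshold scan, three-tier rule |
| `pyrotier.km` | Kaplan–Meier, log-rank, per-tier survival report |
| `pyrotier.pipeline` | orchestration, versioned JSON report |
| `pyrotier.cli` | `pyrotier` command-line interface |

See `docs/methods.md` for the statistical details, default parameter
choices and known limitations.
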