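# caremirt

A validation toolkit for short multidimensional patient-reported outcome
scales, built around the psychometric workflow used to validate a
10-item, five-category resilience instrument for family caregivers of
cancer patients (two correlated latent traits: a *Generic* resilience
factor and a *Shift-Persist* factor). The raw study data behind such
validations are typically not shareable, so the package pairs every
analysis stage with a synthetic-cohort generator and simulation studies
that verify each stage recovers known truth.

## What it implements

**The measurement model.** The compensatory multidimensional graded
response model (MGRM-C): the probability that person *j* answers item
*i* in category *k* or above is

```
P*_ijk = exp(a_i·θ_j + d_ik) / (1 + exp(a_i·θ_j + d_ik))
```

with discrimination vector `a_i` (structurally zero off the item's
factor), easiness intercepts `d_ik` (strictly decreasing in *k*), and
trait vector `θ_j`. Category probabilities are first differences of the
cumulative sequence. Estimation is EM / marginal maximum likelihood on a
Gauss–Hermite grid (deterministic; latent variances fixed at 1, the
between-factor correlation free) with an optional
Metropolis-within-Gibbs MCMC mode. A between-item two-factor structure
and an orthogonal bifactor structure can be fitted and compared
(log-likelihood, AIC/BIC/SABIC, LR test, and a veto on bifactor
solutions showing negative specific slopes — the signature of
information over-extraction).

**Around the model:**

- item diagnostics: multidimensional discrimination `MDISC = ‖a_i‖` with
  the poor/moderate/good/excellent cut-points, multidimensional
  difficulty `MDIFF_k = −d_ik / MDISC`, threshold-ordering checks,
  Yen's Q3 local-independence screen (mean-centered, 0.20 cut),
  expected-score / information / standard-error surfaces;
- differential item functioning between two groups via the iterative
  hybrid ordinal-logistic-regression/IRT approach with Monte-Carlo
  empirical thresholds and purification, plus test-characteristic-curve
  impact summaries;
- latent profile analysis (Gaussian mixtures, K = 1..5, AIC/BIC/entropy,
  adjusted LMR and parametric-bootstrap LRT, auditable class-count
  recommendation);
- the resilience→quality-of-life link: SF-36 domain handling and
  dichotomization, descriptive cohort tables, a penalized-spline
  logistic GAM testing non-linearity, and crude / covariate-adjusted /
  per-SD dose-response odds ratios across resilience classes;
- a synthetic cohort generator reproducing the published cohort's
  margins (n = 382; e.g. 75.4% spouses, 59.9% women) with configurable
  truth: latent correlation, DIF injection, class mixtures, and a
  monotone QoL link whose true per-SD odds ratio defaults to 1.6.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/06_dose_response.py` simulates a 382-person cohort with
a true per-SD odds ratio of 1.6 and prints:

```
GAM smooth EDF = 1.00, non-linearity p = 0.864 (EDF near 1: this draw is compatible with a linear logit)
       contrast    or  ci_low  ci_high  p_value    model
         2 vs 1 1.812   1.001    3.278    0.050    crude
         3 vs 1 1.975   1.089    3.583    0.025    crude
         4 vs 1 3.640   2.028    6.535    0.000    crude
         ...
per_sd_adjusted 1.604   1.287    2.001    0.000 adjusted

adjusted class ORs monotone: True
per-SD OR = 1.60 (95% CI 1.29-2.00; true value 1.6)
```

The class odds ratios rise monotonically from the lowest-resilience
reference class and the per-SD estimate brackets the generating value —
the dose-response pattern the generator encodes, recovered by the
analysis.

A full pipeline run (cohort → calibration → diagnostics → DIF → profiles
→ dose-response, with all artifacts and a JSON report) is available from
Python via `caremirt.run_pipeline(PipelineConfig(...))` or from the shell:

```bash
caremirt all --seed 7 --out results/run1
```

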