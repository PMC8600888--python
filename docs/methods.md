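# Methods

This note records the models the package implements, the conventions and
defaults it fixes where the field leaves choices open, and what the
simulation studies do and do not establish.

## The measurement model

The compensatory multidimensional graded response model (MGRM-C) treats
each of the ten items as an ordered five-category response driven by a
two-dimensional latent trait θ = (Generic, Shift-Persist). The
probability of responding in category *k* or above on item *i* is
logistic in the linear predictor `a_i·θ + d_ik`:

- `a_i` — discrimination (slope) vector, structurally zero on factors
  the item does not measure. In the between-item structure each item
  loads on exactly one factor; in the bifactor structure on the general
  factor plus one specific factor.
- `d_ik` — easiness intercepts for boundaries k = 2..K, strictly
  decreasing within an item. Strict descent is what guarantees positive
  category probabilities, so it is enforced structurally during
  estimation (intercepts are parameterized as a free first value minus
  cumulative exponentiated gaps).
- Category probabilities are first differences of the cumulative
  sequence with boundary conventions `P*_1 = 1`, `P*_{K+1} = 0`.
  Categories are 1-based externally and 0-based internally.

"Compensatory" means a deficit on one trait can be offset by the other
through the linear predictor; nothing here transfers to
non-compensatory (product-form) models.

### Identification

Latent variances are fixed at 1. In the between-item model the factor
correlation is free; bifactor factors are mutually orthogonal. These are
the conventions of mainstream MIRT software; the data cannot separate a
slope rescaling from a variance rescaling, so some convention is
mandatory.

### Estimation

The default estimator is EM / marginal maximum likelihood on a fixed
Gauss–Hermite product grid (21 nodes per dimension for two factors, 11
for the three-dimensional bifactor; both configurable). The correlated
prior is handled by reweighting the independent-normal rule by the
density ratio and renormalizing, which keeps the discretized model a
proper finite mixture — and therefore keeps EM monotone, which the
test-suite asserts every cycle. The M-step solves one small weighted
graded-response likelihood per item (L-BFGS with analytic gradients) and
a one-dimensional problem for the factor correlation.

Convergence: maximum absolute parameter change < 1e-4, or 500 cycles.
A secondary stop triggers when the relative marginal-likelihood
improvement falls below 1e-7 (after at least 10 cycles): weakly
identified fits — e.g. a bifactor model on between-item data — drift
along a flat likelihood ridge where parameters move at ~2e-4 per cycle
while the likelihood is already stationary. Starting values are
deterministic (slopes 1 on loaded entries, intercepts from marginal
category logits), so fits are exactly reproducible.

An MCMC mode (Metropolis-within-Gibbs; normal priors N(0, 2²) on loaded
slopes and N(0, 3²) on intercepts, flat prior on the correlation,
ordering enforced by proposal rejection; default cap 4000 cycles,
posterior means reported) targets the same estimand. It exists because
the estimator family used in practice for such scales is MCMC-based; the
deterministic EM is the default because stochastic output cannot anchor
exact tests. The sampler's priors and proposal scales are implementation
choices, documented here, not attributed to any external source.

### Structure comparison

Both structures are fitted and compared on information criteria and a
likelihood-ratio statistic (df = difference in free parameter counts).
The decision rule: keep the parsimonious between-item model unless the
bifactor fits significantly better *and* shows no negative structural
specific slope. A negative specific slope (any value below 0, no
tolerance band) is read as information over-extraction and always
disqualifies the bifactor solution.

One identifiability fact matters for simulation design: a bifactor truth
whose general/specific slope *ratio* is constant within an item block is
likelihood-equivalent to the correlated two-factor model (the two slope
components act through a single direction per block). Bifactor-recovery
simulations therefore use heterogeneous slope ratios; with a constant
ratio no method could, even in principle, distinguish the structures.

## Item diagnostics

- `MDISC = ‖a_i‖` with quality labels poor (< 0.5), moderate
  (0.5–1.0), good (1.0–1.5), excellent (> 1.5); exact boundary values
  take the lower label, read literally from the published cut-point
  text.
- `MDIFF_k = −d_ik / MDISC`: signed distance from the origin, along the
  steepest-ascent direction, to the point where boundary *k* has
  probability one half (verified to 1e-10 in the tests). A strictly
  monotone MDIFF sequence in either direction counts as ordered; the
  direction is reported rather than assumed, because the sign convention
  of the difficulty axis differs across software.
- Local independence: Yen's Q3 — Pearson correlations, across persons,
  of residuals `x_ij − E[x_ij | EAP θ̂_j]`. For a short test the raw Q3
  has a structural expectation near −1/(I−1) ≈ −0.11 even under perfect
  local independence (each item contributes heavily to its own ability
  estimate). Flags are therefore raised on the mean-centered statistic
  (often written Q3\*) against the 0.20 cut; raw values are always
  reported, and `center=False` restores the uncentered reading. With
  centering, the null flag rate at n = 1000 stays at or below chance
  (≤ 5% of the 45 pairs), which is the calibration the test-suite
  checks; without it the structural bias dominates and the screen is
  uninterpretable at this test length.
- Test information is directional: Samejima's graded-response item
  information with `(a_i·u)²` in place of the scalar slope, summed over
  items, for a unit direction `u` (default: equal weights). The
  conditional standard error is `1/√information`. Default evaluation
  grid [−4, 4] per dimension, step 0.1.

## Differential item functioning

The hybrid screen regresses each item's ordered response on a composite
ability (EAP scores projected onto the equal-weight direction and
standardized — the hybrid framework is unidimensional, so the two-factor
score is deliberately reduced), the group indicator, and their
interaction, in three nested proportional-odds models. LR statistics:
group main effect (uniform DIF, df 1), interaction (non-uniform, df 1),
both (df 2); McFadden pseudo-R² changes and the relative change in the
ability coefficient are reported as alternative criteria (cuts 0.02 and
10%), off by default.

Purification iterates: score ability on the current anchor (unflagged)
items, recompute all statistics, rebuild the anchor; stop when the
flagged set stabilizes (cycles broken by preferring the smaller flagged
set), default cap 10 rounds. Monte-Carlo thresholds simulate DIF-free
cohorts from the fitted model at the observed group sizes, run the full
purification pipeline on each, and take the empirical (1−α) quantile of
every statistic per item — so the thresholds price in purification
itself. `alpha=1` returns the minimum simulated statistic (boundary
convention).

The proportional-odds fitter is an in-package L-BFGS maximizer with
analytic gradients and ascending-cutpoint parameterization, written for
the Monte-Carlo inner loops (~4 ms per fit); the test-suite pins it to
statsmodels' `OrderedModel` to ~1e-6 agreement.

TCC impact compares expected total scores under the reference and focal
parameter sets over a trait grid, and converts the score difference to
ability-equivalent units by dividing by the local slope of the reference
curve.

## Latent profiles

Gaussian mixtures over continuous indicators with class-specific means
and, by default, a diagonal within-class covariance shared across
classes (the convention of the mixture software standardly used for
profile analysis; class-varying diagonal variances sit behind a flag).
EM from k-means-seeded starts (default 50), best log-likelihood kept,
classes sorted by profile mean, components with expected share below
1/(10n) treated as degenerate and restarted.

Relative entropy `1 − Σ(−p log p)/(n log K)` summarizes classification
certainty (1 = crisp, 0 = uniform); it is undefined at K = 1.

The K vs K−1 comparison is available two ways. The adjusted LMR-style
statistic `2ΔLL / (1 + Δq/ln n)` referred to chi-square(Δq) is a
deliberately conservative closed-form stand-in — the true reference
distribution for mixture class counts is intractable and published
approximations to it are contested at these sample sizes. The
parametric-bootstrap LRT (simulate from the fitted K-class model, refit
both) is the recommended backend and the one the heavyweight tests use.

Class-count recommendation: the smallest K whose (K+1)-class test is
non-significant, subject to entropy ≥ 0.8 (vacuous at K = 1) and BIC
being a local minimum; if nothing qualifies, the BIC minimizer. The full
enumeration table is always returned so the rule is auditable.
Indicators default to the ten item scores; a trait-score mode exists.

## The QoL link

SF-36 domains are 0–100 scores; dichotomization requires an explicit
normative cut-off (none is shipped — normative values are
population-specific) and defaults to comparing the eight-domain mean to
the composite cut-off, scores at the boundary coding high. Descriptive
tables print counts with within-stratum percentages rounded half-up to
one decimal, the convention of published cohort tables.

Non-linearity is tested with a penalized B-spline logistic GAM
(10 basis functions, cubic): the penalty is chosen from a log-spaced
grid by approximate GCV, the smooth's effective degrees of freedom are
the trace of its hat-matrix block, and a likelihood-ratio comparison
against the plain linear logit (df = EDF − 1, floored at 0.5) gives the
non-linearity p-value. EDF near 1 and a non-significant test mean no
evidence of curvature.

Dose-response: three logistic fits — crude (class dummies), adjusted
(class dummies + dummy-coded covariates; the default covariate set is
every cohort covariate, recorded in the output), per-SD (total score
standardized by the analysis-sample SD, plus covariates). Wald 95%
intervals `exp(β ± 1.96·SE)`. Monotonicity of the adjusted class ORs is
reported as the dose-response check. Per-SD contrasts are omitted when
the score is constant (degenerate input).

## The synthetic cohort generator

The generator encodes the study conditions every simulation uses:

- n = 382 persons; ten items, five categories, 5/5 split across the two
  factors. Which five items belong to which factor is not public for the
  original instrument, so the split is an explicit, configurable
  assumption.
- True slopes {1.6, 1.9, 2.2, 1.4, 2.0, 1.8, 2.4, 1.5, 2.1, 1.7}
  (the well-discriminating 1.4–2.4 range a validated short scale shows),
  intercept base {2.2, 0.9, −0.4, −1.8} with per-item offsets spanning
  ±0.5, latent correlation 0.5.
- Covariates drawn independently from the published cohort margins
  (75.4% spouses, 59.9% women, 61.8% unemployed, ...). Only margins are
  public, so no joint structure is modeled — sufficient for exercising
  adjustment machinery, silent about real-world confounding.
- QoL: the high-QoL probability is a monotone link in the standardized
  total score — logistic with slope ln(1.6) per SD by default (the
  published design point), with flat and plateau-then-rise variants for
  non-linearity studies. Standardization uses the model-implied
  population moments of the total score, computed by quadrature. SF-36
  domains are the link probability scaled to 0–100 plus Gaussian noise
  (sd 10 points), clipped; raw 36-item responses are not emulated.
- DIF injection shifts the target item's intercepts down by the given
  amount for the focal group (harder item) and/or scales its slopes;
  class mixtures shift latent means or generate continuous indicators
  directly.
- One global seed expands into named per-stage child seeds
  (SeedSequence), so every stage is independently regenerable and
  bit-reproducible.

What passing simulations show — and what they do not: recovery at these
design points demonstrates the estimators and screens are correct and
calibrated *under the assumed model*. Real cohorts add missing data,
joint covariate structure, model misspecification and informative
selection, none of which the generator emulates.

## Problem sizes in the validation studies

The acceptance studies use: one n = 2000 cohort for parameter recovery;
n = 1000 for the Q3 null calibration; 200 DIF-free cohorts at 191 per
group (the published cohort's near-even split) against thresholds from
400 calibration simulations, and 100 replicates at 500 per group for
power against a 0.6 threshold shift (thresholds from 300 simulations);
20 replicates at n = 1000 for structure selection; 20 replicates at
n = 400 with 4-SD class separation for profile recovery; 200 replicates
at n = 382 for the per-SD odds ratio and 100 at n = 400 for GAM power.
These sizes give Monte-Carlo error comfortably inside the asserted
margins while keeping a full run in the tens of minutes on one CPU.

## Known limitations

- Non-compensatory MGRMs, more than two DIF groups, categorical-
  indicator latent class models and growth mixtures are out of scope.
- The adjusted LMR approximation is conservative by construction; use
  the bootstrap backend for decisions.
- Monte-Carlo DIF thresholds inherit quantile noise of order ±0.3–0.5
  (chi-square units) at a few hundred calibration simulations; type-I
  error is controlled on average across items, not exactly per item.
- The MCMC estimator is provided for methodological parity and smoke-
  tested only; its defaults are not tuned for production posterior
  inference.
- Real-data fit indices (AIC of a published calibration, observed
  entropy values, observed DIF p-values) depend on data that are not
  public and are deliberately not targets of any test here.
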