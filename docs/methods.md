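# Methods

## Model

The follow-up score Y takes values in {0, …, K}.  Conditional on the
baseline score y⁰, a stratum s, and the treatment indicator x, the model
for the conditional distribution function is

    P(Y ≤ y | y⁰, s, x) = expit( h(y | y⁰, s) + β·x ).

The likelihood contribution of one subject is the probability mass

    expit(h(y) + βx) − expit(h(y−1) + βx),

with the boundary conventions h(−1) = −∞ and h(K) = +∞ so the lowest and
highest categories use one-sided terms.  exp(β) is a single global odds
ratio (lower-or-equal odds, treated : control) that holds at every cut-off
— the proportional odds assumption.  The package reports both exp(β) and
exp(−β) (the "benefit" direction, > 1 meaning stochastically larger
outcomes under treatment) with explicit labels, because both conventions
circulate in practice.

### Transformation function

h is parameterized as a(⌊y⌋)ᵀϑ where a(·) is a Bernstein basis of P
functions (degree P−1) on [0, K], tensored with a dummy coding of strata
and the response-varying covariate vector (1, m), m being the baseline
score rescaled to [0, 1] by its declared theoretical range.  The basis
interval is [0, K] because every supported outcome scale starts at 0.
Total parameter count: P × S × C (42 for P = 7, three strata, two
covariates).  Defaults: P = 7; configurable per model.

Monotonicity in y must hold for every admissible baseline value.  Since h
is affine in m, it suffices that the implied Bernstein coefficient vector
is increasing at both extremes m = 0 and m = 1; these per-block linear
constraints are what `monotonicity_constraints` describes and what the
optimizer enforces.

### Estimation

Each constrained block is parameterized as (first coefficient,
increments), with the increments kept ≥ 1e−8 by box constraints, and the
whole problem is solved by projected quasi-Newton (L-BFGS-B) with analytic
gradients; one restart with fresh curvature memory guards against
premature termination in the long shallow valleys that weakly identified
transformation directions produce.  An earlier design mapped increments
through an exponential to obtain a fully unconstrained problem; that map
is badly conditioned whenever an increment approaches zero (the optimizer
stalls on plateaus and different memory settings reach visibly different
optima), so the box-constrained form is used instead.  Convergence
tolerances: projected gradient 1e−8, at most 1000 iterations.

ϑ is initialized from the empirical marginal logit-CDF of the outcome on
the Bernstein grid, per stratum, with zero baseline slope; β starts at 0.
The covariance of the estimates is the inverse observed information — a
central-difference Hessian of the objective in the optimization
coordinates, mapped back to (β, ϑ) by the delta method; a pseudo-inverse
is used so that structurally unidentified directions (e.g. the unused
second Bernstein coefficient when K = 1) do not contaminate the identified
block.  Log-probabilities use a stable log-difference-of-expits
formulation throughout.

A stratum with fewer than two distinct outcome values makes h
unidentifiable there and raises an error; fewer observations than basis
parameters only triggers a warning, mirroring how such models are used in
small trials.

### Inference

* **Wald**: z = β̂/se, two-sided normal p, multiplicatively symmetric CI
  on the OR scale.  Known to be liberal in small samples.
* **Permutation score test**: from the intercept-only fit, each subject's
  score is the closed-form derivative of their log-likelihood with respect
  to a treatment shift at zero,
  Sᵢ = [w(h(yᵢ)) − w(h(yᵢ−1))] / [expit(h(yᵢ)) − expit(h(yᵢ−1))], w the
  expit derivative (validated against finite differences in the tests; the
  score sum vanishes at the null MLE because the intercept direction lies
  in the model span).  T = Σ treated Sᵢ is centered at its exact
  conditional mean n₁·S̄ and compared two-sidedly against label
  permutations that preserve group sizes; the p-value uses the add-one
  estimator (b+1)/(B+1), which cannot be exactly zero.  Permutations are
  simple label shuffles by default — stratification enters through the
  null model's h — with within-stratum shuffling available as an option.
  With the fixed rank transformation h(yᵢ) = logit(Rᵢ/N) (upranks Rᵢ) the
  scores reduce to 1 − (2Rᵢ−1)/N on tie-free data, i.e. Wilcoxon scores,
  which the tests exploit as an independent oracle.

## Trial simulation and power

`estimate_power` fits the intercept-only model once to a treatment-naive
pool, then per replicate resamples N subjects **with replacement**
(baselines and strata kept), allocates them 1:1, and draws every subject's
follow-up from the fitted conditional distributions — controls at OR = 1,
treated shifted by −log(OR_benefit).  Drawing both arms from the generator
keeps each simulated trial exactly exchangeable under the null, so the
permutation test's level is guaranteed by construction; keeping observed
control outcomes instead would be an equally defensible reading and
coincides in distribution at OR = 1.  Five tests are applied per trial:

1. pooled t-test on change scores (N−2 df),
2. Wilcoxon rank-sum on change scores (tie-corrected normal approximation
   with continuity correction),
3. ANCOVA — OLS of follow-up on baseline and arm, testing the arm term,
4. the asymptotic (Wald) test of the refitted treatment model,
5. the permutation score test of the refitted intercept-only model.

The default grid is 5 trial sizes {80, 120, 160, 200, 240} × 9 benefit ORs
{1, 1.25, …, 3} = 45 scenarios, 1:1 allocation.  Rejection fractions at
α = 0.05 are reported with 95% Wilson score intervals.  The per-scenario
replicate count is a parameter: the package default of 1000 gives Wilson
half-widths near ±0.03 at power 0.5; production-scale studies of this
design have used an order of magnitude more ("15,000 replications of the
45 scenarios" admits both a per-scenario and a total reading; the package
leaves the count explicit rather than resolving that ambiguity).  One
master seed spawns independent per-scenario and per-replicate RNG streams,
so any scenario is reproducible in isolation.  Degenerate simulated trials
(all outcomes equal) make every test return p = 1 with a warning; a failed
model refit is recorded as a missing p-value and excluded from the
rejection fraction (the effective replicate count is reported).

## Synthetic cohorts

Real cohorts of this kind are not redistributable, so the generator
emulates their stated structure with a known ground truth that lies
*exactly* in the fitted model family — the target shape
a_s + slope·logit((y+½)/(K+1)) + c·m is projected onto the Bernstein basis
once (with a monotone repair of numerically non-monotone projections), so
parameter-recovery and coverage tests are fair tests of the estimator
rather than of spline approximation error.

Presets: motor score (K = 50, baseline 0–28, three segment-band strata
[0,6]/[7,8]/[9,10] from a uniform 4–10 segment count), independence
measure total (K = 100) and self-care subscore (K = 20), both single
stratum by default (strata can be forced on any preset).  Baselines follow
a discretized Beta(1.2, 3.5) on the preset range — right-skewed and
bounded, as such scores are in early post-injury cohorts.  Defaults chosen
once for realism: slope 1.8 (outcome dispersion of a few categories),
baseline effect −10 logits across the full baseline range (Spearman
baseline–follow-up ≈ 0.55–0.6, the strong positive dependence that makes
baseline adjustment worthwhile), stratum offsets (0, −2, −4) logits
(substantially different recovery distributions per injury level, which is
the stated reason stratification matters for motor scores).  Treatment
enters as −log(OR_benefit) on the lower-or-equal scale.

What the generator does *not* emulate: assessment-time windows, item-level
structure, missingness, floor/ceiling clumping beyond what the smooth
model produces, or any estimate of a real cohort's marginal distributions.
Passing tests therefore demonstrate correctness of the estimator and the
operating characteristics *under the model*, not the numeric power values
any specific registry would give.

## Problem sizes used in the test-suite

Chosen as the package's own desk-scale defaults: the type-I error check
runs 1000 null trials of N = 80 with 1000 permutations each (self-care
preset — the cheapest of the three model forms to refit per trial);
Wald coverage uses 200 cohorts of N = 2000 at benefit ORs 1.5 and 2; the
power sweep runs 300 replicates per scenario on a reduced
{80, 240} × {1, 2, 3} grid with a stratified K = 20, P = 5 configuration.
Oracle equivalences (logistic reduction, exhaustive 924-allocation
enumeration on a 12-subject fixture, Wilcoxon rank-sum decisions on 500
small datasets) are exact-scale.

## Known limitations

* Proportional odds is assumed, not tested; no non-logit links.
* One binary treatment term besides the strata; no repeated-measures or
  longitudinal trajectories.
* The Wald covariance treats active monotonicity constraints as if
  interior; when many increments sit at the 1e−8 floor (tiny strata,
  small K) standard errors are approximate.  The permutation test does not
  share this caveat.
* Standard errors may differ in the third decimal from implementations
  using the expected information or a different optimizer.
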