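# epolr — baseline-adjusted proportional odds models for ordinal sum-score trials

Randomized trials in neurology and rehabilitation often use ordinal sum
scores as primary outcomes — e.g. an upper-extremity motor score (0–50) or
an independence measure (0–100) after spinal cord injury.  The routine
analyses (t-test or rank-sum test on change scores, ANCOVA on the follow-up
score) either ignore the ordinal nature of the scale or cannot use baseline
information, and a classical proportional odds model would need one
intercept per outcome category and stratum — far more parameters than
subjects.

`epolr` implements an *enhanced* proportional odds model for a follow-up
score Y ∈ {0, …, K} with baseline score y⁰, stratum s, and treatment
indicator x ∈ {0, 1}:

    P(Y ≤ y | y⁰, s, x) = expit( h(y | y⁰, s) + β·x )

The category intercepts are replaced by a smooth monotone transformation
h, parameterized by a Bernstein polynomial in ⌊y⌋ tensored with stratum
dummies and a response-varying baseline covariate (1, y⁰): with P basis
terms, S strata and two covariates that is P·S·2 parameters (7×3×2 = 42 in
the stratified motor-score model).  All parameters, including the single
global treatment log-odds ratio β, are estimated jointly by maximum
likelihood under a monotonicity constraint on h.  exp(β) is the odds of
scoring *at or below* any cut-off (treated : control); exp(−β) is the same
effect on the **benefit** scale — values above 1 mean stochastically larger
(better) outcomes under treatment.  Both directions are always reported.

Inference comes in two flavors:

* **asymptotic (Wald) test** — CI and p-value from the inverse observed
  information; interpretable but somewhat liberal in small trials;
* **permutation score test** — score contributions Sᵢ = ∂ℓᵢ/∂α|₀ are
  extracted from the intercept-only null fit and the treated-arm score sum
  is compared with its label-permutation distribution; this keeps the
  nominal level at any sample size.  With a fixed rank transformation the
  same construction reduces to the Wilcoxon rank-sum test.

A parametric-bootstrap simulator estimates power and sample size for
planned two-arm trials: subjects are resampled from a treatment-naive pool,
follow-ups are drawn from the fitted null model shifted by a postulated
benefit odds ratio, and five tests (t, Wilcoxon, ANCOVA, Wald, permutation)
are applied over a grid of 5 trial sizes × 9 odds ratios (45 scenarios),
with Wilson confidence intervals on every rejection rate.  Because the real
registry data behind such analyses are not redistributable, the package
ships a synthetic-cohort generator with a known ground-truth model against
which everything is validated.

## Worked example

```python
import numpy as np
from epolr import CohortConfig, generate_cohort, fit, wald_inference

table, truth = generate_cohort(CohortConfig(
    preset="uems", n_subjects=350, beta_benefit=np.log(2), seed=1))
result = fit(table, truth["spec"])
wald = wald_inference(result)
print(f"benefit OR {wald.or_benefit:.3f}, CI {wald.or_benefit_ci}, "
      f"p = {wald.p_value:.4f}")
```

prints

```
benefit OR 1.510, CI (1.013, 2.253), p = 0.0431
```

i.e. the treated arm's odds of exceeding any motor-score cut-off are
estimated 1.51 times the control arm's (the generator's true value is 2.0;
the 95% CI excludes 1, so the effect is detected at the 5% level).  The
scripts in `examples/` walk through each capability — cohort simulation,
model fitting, the permutation test, and a small power grid — and print a
line explaining every number.  A thin CLI mirrors the same workflows:

```sh
epolr simulate-cohort --preset uems --n 350 --beta-benefit 0.693 --seed 1 --out cohort.csv
epolr fit  --data cohort.csv --k-max 50 --baseline-range 0,28
epolr test --data cohort.csv --k-max 50 --baseline-range 0,28 --n-perm 10000 --seed 42
epolr power --data cohort.csv --k-max 50 --baseline-range 0,28 --reps 1000 --seed 7 --out power.csv
```

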