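"""Fit the baseline-adjusted proportional odds model to a two-arm trial.

A single global odds ratio summarizes the treatment effect across the whole
ordinal scale: exp(-beta) > 1 means the treated arm's outcomes are
stochastically larger at every cut-off, after adjusting for baseline score
and stratum.
"""

import numpy as np

from epolr import CohortConfig, fit, generate_cohort, wald_inference

table, truth = generate_cohort(CohortConfig(
    preset="uems", n_subjects=350, beta_benefit=np.log(2), seed=1))
spec = truth["spec"]

result = fit(table, spec)
wald = wald_inference(result)

print(f"n = {result.n_obs}, log-likelihood = {result.loglik:.2f}, "
      f"converged = {result.converged}")
print(f"transformation parameters: {spec.n_theta} "
      f"({spec.n_params} basis x {spec.n_strata} strata x "
      f"{spec.n_covariates} covariates)")
print(f"\nbenefit odds ratio exp(-beta) = {wald.or_benefit:.3f} "
      f"(95% CI {wald.or_benefit_ci[0]:.3f} to {wald.or_benefit_ci[1]:.3f})")
print(f"true value used by the generator: "
      f"{np.exp(truth['beta_benefit']):.3f}")
print(f"Wald z = {wald.z:.2f}, two-sided p = {wald.p_value:.4f}")
print("\nA benefit OR above 1 with a CI excluding 1 indicates the treated")
print("arm recovers to higher scores than controls with the same baseline.")
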