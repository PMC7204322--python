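"""Simulation-based power and sample-size assessment for a planned trial.

Trials are simulated by resampling subjects from a treatment-naive pool and
drawing treated follow-ups from the fitted null model shifted by a
postulated benefit odds ratio; five tests are applied to every simulated
trial.  A reduced grid is used here so the example runs in about a minute;
the full design grid is 5 sizes x 9 odds ratios.
"""

from epolr import (
    CohortConfig,
    TrialScenario,
    estimate_power,
    generate_cohort,
    power_frame,
)

pool, truth = generate_cohort(CohortConfig(
    preset="scim_selfcare", n_subjects=350, seed=42, stratified=True,
    order=5))

scenarios = [TrialScenario(n_total=n, or_benefit=r, n_reps=150, seed=n + int(10 * r))
             for n in (80, 160) for r in (1.0, 2.0)]
estimates = estimate_power(scenarios, pool, truth["spec"], n_perm=500)

df = power_frame(estimates)
print(df.to_string(index=False,
                   formatters={"power": "{:.3f}".format,
                               "wilson_lo": "{:.3f}".format,
                               "wilson_hi": "{:.3f}".format}))
print("\nEach row: fraction of simulated trials (with 95% Wilson CI) in")
print("which that test rejected at alpha = 0.05.  At or_benefit = 1 the")
print("fraction should sit near 0.05 (type-I error); at 2 it is power.")
print("The model-based tests exploit baseline and stratum information the")
print("rank and mean-difference tests cannot, hence their higher power.")
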