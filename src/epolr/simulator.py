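"""Parametric-bootstrap trial simulation, test battery, and power curves.

A two-arm trial is simulated by resampling subjects (baseline, stratum) from
a treatment-naive pool, allocating them 1:1, and drawing new follow-up
scores from the conditional distributions of an intercept-only model fitted
to the pool — shifted by a postulated benefit odds ratio for the treated
arm.  Each simulated trial is analyzed with five tests of no treatment
effect, and power is the rejection fraction at the nominal level with a
Wilson score confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from . import model as _model
from .model import CohortTable, EPolrFit, fit, wald_inference
from .permutation import permutation_test, score_contributions
from .transform import TransformationSpec

__all__ = [
    "TrialScenario",
    "PowerEstimate",
    "TEST_NAMES",
    "default_grid",
    "wilson_ci",
    "sample_outcomes",
    "run_test_battery",
    "estimate_power",
    "power_frame",
]

TEST_NAMES = ("asymptotic_epolr", "permuted_epolr", "t_test", "wilcoxon",
              "ancova")

#: default simulation grid: five trial sizes by nine benefit odds ratios
DEFAULT_SIZES = (80, 120, 160, 200, 240)
DEFAULT_ORS = (1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5, 2.75, 3.0)


@dataclass(frozen=True)
class TrialScenario:
    n_total: int
    or_benefit: float
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.or_benefit <= 0:
            raise ValueError("or_benefit must be positive")
        if self.n_total < 4:
            raise ValueError("n_total too small for a two-arm trial")


@dataclass(frozen=True)
class PowerEstimate:
    scenario: TrialScenario
    test_name: str
    power: float
    wilson_lo: float
    wilson_hi: float
    n_reps_effective: int


def default_grid(n_reps: int = 1000, seed: int = 0,
                 sizes=DEFAULT_SIZES, ors=DEFAULT_ORS) -> list[TrialScenario]:
    """The full factorial grid of trial scenarios (default 5 x 9 = 45)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sizes) * len(ors))
    out = []
    i = 0
    for n in sizes:
        for r in ors:
            out.append(TrialScenario(n_total=n, or_benefit=r, n_reps=n_reps,
                                     seed=int(children[i].generate_state(1)[0]
                                              % (2**31 - 1))))
            i += 1
    return out


def wilson_ci(successes: int, n: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level,
                                method="wilson")
    # the Wilson bound is exactly 0 (resp. 1) at the boundary counts
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return lo, hi


# --------------------------------------------------------------------------
# parametric bootstrap
# --------------------------------------------------------------------------

def _cdf_lookup(null_fit: EPolrFit, subjects: CohortTable) -> np.ndarray:
    """Per-subject h(y) rows over {0..k_max-1} under the null fit;
    CDF = expit(H + shift), appended with 1."""
    return _model._h_grid(null_fit, null_fit.spec, subjects.baseline,
                          subjects.stratum)


def sample_outcomes(null_fit: EPolrFit, subjects: CohortTable,
                    or_benefit: float, rng) -> np.ndarray:
    """Draw new follow-up scores for every subject under a postulated
    benefit odds ratio (treated arm shifted by ``-log(or_benefit)``;
    controls are drawn at odds ratio 1)."""
    if or_benefit <= 0:
        raise ValueError("or_benefit must be positive")
    rng = np.random.default_rng(rng)
    H = _cdf_lookup(null_fit, subjects)
    shift = np.where(subjects.arm == 1, -np.log(or_benefit), 0.0)
    from scipy.special import expit
    cdf = np.concatenate(
        [expit(H + shift[:, None]), np.ones((len(subjects), 1))], axis=1)
    u = rng.random(len(subjects))
    return (u[:, None] > cdf).sum(axis=1)


# --------------------------------------------------------------------------
# test battery
# --------------------------------------------------------------------------

def _degenerate(p_default: float = 1.0) -> dict:
    return {name: p_default for name in TEST_NAMES}


def run_test_battery(trial: CohortTable, spec: TransformationSpec, *,
                     n_perm: int = 10_000, seed: int = 0,
                     fit_kwargs: dict | None = None) -> dict:
    """Five p-values for H0: no treatment effect on one simulated trial.

    (1) pooled two-sample t-test on change scores, (2) Wilcoxon rank-sum on
    change scores (tie-corrected normal approximation with continuity
    correction), (3) ANCOVA of follow-up on baseline plus arm, (4) Wald test
    from the treatment-effect model fit, (5) permutation score test from the
    intercept-only fit.
    """
    if trial.arm.min() == trial.arm.max():
        raise ValueError("trial must contain both arms")
    fit_kwargs = fit_kwargs or {}

    if np.ptp(trial.outcome) == 0:
        warnings.warn("degenerate trial: all outcomes equal; returning p=1",
                      UserWarning, stacklevel=2)
        return _degenerate()

    change = trial.outcome.astype(float) - trial.baseline
    ch_t = change[trial.arm == 1]
    ch_c = change[trial.arm == 0]

    out = {}
    # t-test on change scores (pooled variance, N-2 df)
    if np.ptp(change) == 0:
        out["t_test"] = 1.0
        out["wilcoxon"] = 1.0
    else:
        out["t_test"] = float(stats.ttest_ind(ch_t, ch_c, equal_var=True)
                              .pvalue)
        out["wilcoxon"] = float(stats.mannwhitneyu(
            ch_t, ch_c, alternative="two-sided", use_continuity=True,
            method="asymptotic").pvalue)

    # ANCOVA: outcome ~ baseline + arm
    X = sm.add_constant(np.column_stack([trial.baseline, trial.arm]))
    ols = sm.OLS(trial.outcome.astype(float), X).fit()
    out["ancova"] = float(ols.pvalues[2])

    # model-based tests
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        try:
            alt = fit(trial, spec, include_treatment=True, **fit_kwargs)
            out["asymptotic_epolr"] = float(wald_inference(alt).p_value)
        except Exception as err:  # noqa: BLE001 - record, don't kill a sweep
            warnings.warn(f"asymptotic ePolr test failed: {err}", UserWarning)
            out["asymptotic_epolr"] = np.nan
        try:
            null = fit(trial, spec, include_treatment=False,
                       compute_vcov=False, **fit_kwargs)
            s = score_contributions(null, trial)
            out["permuted_epolr"] = permutation_test(
                s, trial.arm, n_perm=n_perm, seed=seed).p_value
        except Exception as err:  # noqa: BLE001
            warnings.warn(f"permutation ePolr test failed: {err}", UserWarning)
            out["permuted_epolr"] = np.nan
    return out


# --------------------------------------------------------------------------
# power estimation
# --------------------------------------------------------------------------

def estimate_power(scenarios, base_cohort: CohortTable,
                   spec: TransformationSpec, *, alpha: float = 0.05,
                   n_perm: int = 1000,
                   fit_kwargs: dict | None = None,
                   progress: bool = False) -> list[PowerEstimate]:
    """Rejection fraction per test and scenario, with Wilson intervals.

    The generator model (intercept-only) is fitted once to the
    treatment-naive pool; each replicate resamples ``n_total`` subjects with
    replacement, allocates them 1:1, simulates follow-up scores from the
    generator under the scenario's benefit odds ratio, re-estimates the
    models on the simulated trial and applies the test battery.
    """
    gen_fit = fit(base_cohort, spec, include_treatment=False,
                  compute_vcov=False, **(fit_kwargs or {}))
    results: list[PowerEstimate] = []
    for sc in scenarios:
        if sc.n_reps < 100:
            warnings.warn("n_reps < 100: Wilson intervals will be wide",
                          UserWarning, stacklevel=2)
        ss = np.random.SeedSequence(sc.seed)
        rejected = {name: 0 for name in TEST_NAMES}
        effective = {name: 0 for name in TEST_NAMES}
        for rep, child in enumerate(ss.spawn(sc.n_reps)):
            rng = np.random.default_rng(child)
            idx = rng.integers(0, len(base_cohort), size=sc.n_total)
            n_trt = sc.n_total // 2
            arm = np.zeros(sc.n_total, dtype=int)
            arm[rng.permutation(sc.n_total)[:n_trt]] = 1
            subjects = CohortTable(
                baseline=base_cohort.baseline[idx],
                outcome=base_cohort.outcome[idx],
                stratum=base_cohort.stratum[idx],
                arm=arm,
            )
            y_new = sample_outcomes(gen_fit, subjects, sc.or_benefit, rng)
            trial = subjects.with_outcome(y_new)
            pvals = run_test_battery(
                trial, spec, n_perm=n_perm,
                seed=int(child.generate_state(1)[0] % (2**31 - 1)),
                fit_kwargs=fit_kwargs)
            for name, p in pvals.items():
                if np.isfinite(p):
                    effective[name] += 1
                    rejected[name] += p < alpha
        for name in TEST_NAMES:
            n_eff = max(effective[name], 1)
            pw = rejected[name] / n_eff
            lo, hi = wilson_ci(rejected[name], n_eff)
            results.append(PowerEstimate(
                scenario=sc, test_name=name, power=pw,
                wilson_lo=lo, wilson_hi=hi,
                n_reps_effective=effective[name]))
        if progress:
            print(f"scenario N={sc.n_total} OR={sc.or_benefit}: done")
    return results


def power_frame(estimates) -> pd.DataFrame:
    """Tidy frame of power estimates (one row per scenario x test)."""
    return pd.DataFrame([
        {
            "n_total": e.scenario.n_total,
            "or_benefit": e.scenario.or_benefit,
            "test": e.test_name,
            "power": e.power,
            "wilson_lo": e.wilson_lo,
            "wilson_hi": e.wilson_hi,
            "n_reps": e.n_reps_effective,
        }
        for e in estimates
    ])
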