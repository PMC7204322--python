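"""Synthetic spinal-cord-injury-like cohorts with known ground truth.

Real registry data of this kind (UEMS, SCIM sum scores with baselines and
level-of-injury strata) is not redistributable, so every other module is
exercised on cohorts drawn from a known data-generating process.  The
generator draws a right-skewed discrete baseline score, a number of affected
segments collapsed to three strata, and a follow-up score from an exact
proportional-odds transformation model: the true ``h`` is a monotone
Bernstein polynomial per stratum whose shape follows a logistic-quantile
curve, with an affine effect of the (scaled) baseline score.  Treatment
shifts the log-odds of lower-or-equal scores by ``-log(or_benefit)``, so a
benefit odds ratio above 1 makes outcomes stochastically larger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from .model import CohortTable, _bernstein_matrix, _c_to_theta
from .transform import OrdinalScale, TransformationSpec

__all__ = [
    "PRESETS",
    "CohortConfig",
    "default_spec",
    "generate_cohort",
    "true_cdf",
    "fixture_small_trial",
]

#: outcome presets: (k_max, baseline score range, strata labels or None)
PRESETS = {
    "uems": {"k_max": 50, "baseline_range": (0, 28),
             "strata": ("seg[0,6]", "seg[7,8]", "seg[9,10]")},  # = SEG_BANDS
    "scim_total": {"k_max": 100, "baseline_range": (0, 100), "strata": None},
    "scim_selfcare": {"k_max": 20, "baseline_range": (0, 20), "strata": None},
}


@dataclass(frozen=True)
class CohortConfig:
    """Conditions under which a synthetic cohort is generated.

    ``beta_benefit`` is the true treatment effect as a log odds ratio on the
    benefit scale (0 means no effect).  ``slope`` controls the dispersion of
    the follow-up score around its conditional center; ``baseline_effect``
    is the log-odds shift across the full baseline range (negative values
    give the positive baseline -> follow-up dependence seen in recovery
    data); ``stratum_offsets`` shift ``h`` per stratum.
    """

    preset: str = "uems"
    n_subjects: int = 350
    beta_benefit: float = 0.0
    seed: int = 0
    order: int = 7
    slope: float = 1.8
    baseline_effect: float = -10.0
    stratum_offsets: tuple = (0.0, -2.0, -4.0)
    baseline_shape: tuple = (1.2, 3.5)   # Beta params of the baseline law
    stratified: Optional[bool] = None    # None: preset default

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
            )


SEG_BANDS = ("seg[0,6]", "seg[7,8]", "seg[9,10]")


def default_spec(preset: str, order: int = 7,
                 stratified: Optional[bool] = None) -> TransformationSpec:
    """The model specification matching a cohort preset: three
    segment-band strata for the motor score, a single stratum for the
    independence measures, always with a response-varying baseline effect.
    ``stratified`` overrides the preset's default strata choice."""
    info = PRESETS[preset]
    if stratified is None:
        strata = info["strata"] if info["strata"] else ("all",)
    else:
        strata = SEG_BANDS if stratified else ("all",)
    return TransformationSpec(
        scale=OrdinalScale(info["k_max"]),
        strata_levels=strata,
        n_params=order,
        baseline_varying=True,
        baseline_range=tuple(float(v) for v in info["baseline_range"]),
    )


def _true_theta(config: CohortConfig, spec: TransformationSpec) -> np.ndarray:
    """Project the target transformation onto the Bernstein basis so the
    generating model lies exactly in the fitted family.

    Target per stratum: ``a_s + slope * logit((y + 0.5) / (k_max + 1))``
    plus ``baseline_effect * m`` with m the scaled baseline.
    """
    k = spec.scale.k_max
    grid = np.arange(k)
    target = config.slope * logit((grid + 0.5) / (k + 1.0))
    A = _bernstein_matrix(grid, spec)
    base_coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    # monotone repair (the projection of a monotone curve can wiggle)
    for p in range(1, len(base_coef)):
        base_coef[p] = max(base_coef[p], base_coef[p - 1] + 1e-6)

    nb = spec.n_strata * 2
    c = np.empty((spec.n_strata, 2, spec.n_params))
    for si in range(spec.n_strata):
        a_s = config.stratum_offsets[si % len(config.stratum_offsets)]
        c[si, 0] = base_coef + a_s                           # m = 0
        c[si, 1] = base_coef + a_s + config.baseline_effect  # m = 1
    return _c_to_theta(c.reshape(nb * spec.n_params), spec)


def true_cdf(theta: np.ndarray, spec: TransformationSpec, baseline: float,
             stratum, beta_lte: float = 0.0) -> np.ndarray:
    """Analytic conditional CDF over ``{0..k_max}`` of the generating model
    (``beta_lte`` on the lower-or-equal scale, i.e. -log benefit OR)."""
    from .model import _h_values
    h = _h_values(theta, spec, baseline, stratum)
    return np.append(expit(h + beta_lte), 1.0)


def _sample_from_cdf(cdf_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(cdf_rows.shape[0])
    return (u[:, None] > cdf_rows).sum(axis=1)


def generate_cohort(config: CohortConfig):
    """Draw a two-arm cohort; returns ``(CohortTable, ground_truth)``.

    ``ground_truth`` records the exact generating parameters: the spec, the
    flat true theta, the benefit log-OR and the seed.
    """
    rng = np.random.default_rng(config.seed)
    spec = default_spec(config.preset, config.order, config.stratified)
    info = PRESETS[config.preset]
    n = config.n_subjects

    lo, hi = info["baseline_range"]
    raw = rng.beta(*config.baseline_shape, size=n)
    baseline = np.minimum((raw * (hi - lo + 1)).astype(int) + lo, hi)

    seg = rng.integers(4, 11, size=n)
    if spec.n_strata > 1:
        bands = spec.strata_levels
        stratum = np.where(seg <= 6, bands[0],
                           np.where(seg <= 8, bands[1],
                                    bands[2])).astype(object)
    else:
        stratum = np.array(["all"] * n, dtype=object)

    arm = np.zeros(n, dtype=int)
    treated = rng.permutation(n)[: n // 2]
    arm[treated] = 1

    theta = _true_theta(config, spec)
    beta_lte = -config.beta_benefit      # model scale: P(Y<=y)=expit(h+beta*x)
    from .model import _h_grid
    H = _h_grid(theta, spec, baseline, stratum)
    cdf = np.concatenate(
        [expit(H + (beta_lte * arm)[:, None]), np.ones((n, 1))], axis=1)
    outcome = _sample_from_cdf(cdf, rng)

    table = CohortTable(baseline=baseline, outcome=outcome,
                        stratum=stratum, arm=arm)
    ground_truth = {
        "spec": spec,
        "theta": theta,
        "beta_benefit": config.beta_benefit,
        "beta_lte": beta_lte,
        "seed": config.seed,
        "config": config,
    }
    return table, ground_truth


def fixture_small_trial(seed: int = 7) -> CohortTable:
    """Deterministic 12-subject trial (6 per arm, k_max = 10): small enough
    for exhaustive-permutation oracles (C(12,6) = 924 allocations) and
    hand-checkable likelihoods."""
    rng = np.random.default_rng(seed)
    baseline = rng.integers(0, 11, size=12)
    k = 10
    # follow-up positively dependent on baseline, bounded to the scale
    noise = rng.integers(-2, 4, size=12)
    outcome = np.clip(baseline + noise, 0, k)
    arm = np.array([0, 1] * 6)
    stratum = np.array(["all"] * 12, dtype=object)
    return CohortTable(baseline=baseline, outcome=outcome,
                       stratum=stratum, arm=arm)
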