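"""Model-based permutation score test of no treatment effect.

Under the null, the intercept-only model is fitted and each subject's score
contribution

    S_i = d l_i(alpha) / d alpha  at alpha = 0
        = [ w(h(y_i)) - w(h(y_i - 1)) ] / [ expit(h(y_i)) - expit(h(y_i - 1)) ]

is extracted, where ``w`` is the derivative of expit and ``h`` is the null
fit's stratified transformation.  The test statistic is the sum of scores in
the treated arm; its conditional null distribution is approximated by
re-randomizing the arm labels.  With the fixed rank transformation
``h(y_i) = logit(R_i / N)`` (upranks ``R_i``) the same construction yields
the Wilcoxon rank-sum scores, which is used as a cross-check in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .model import CohortTable, EPolrFit, _design_matrices, _theta_to_c

__all__ = [
    "ScoreVector",
    "PermutationResult",
    "score_contributions",
    "permutation_test",
    "wilcoxon_score_transform",
]


@dataclass(frozen=True)
class ScoreVector:
    """Per-subject score contributions plus provenance of the null fit."""

    scores: np.ndarray
    source: str = "epolr-null-fit"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite score contributions")
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class PermutationResult:
    observed_T: float
    z: float
    p_value: float
    n_perm: int
    seed: int


def _scores_from_h(hb: np.ndarray, ha: np.ndarray) -> np.ndarray:
    """Score contributions from the two cut-point values of h per subject,
    honoring the +-inf boundary conventions (w(+-inf) = 0)."""
    Fb = np.where(np.isposinf(hb), 1.0, expit(hb))
    Fa = np.where(np.isneginf(ha), 0.0, expit(ha))
    wb = np.where(np.isfinite(hb), Fb * (1.0 - Fb), 0.0)
    wa = np.where(np.isfinite(ha), Fa * (1.0 - Fa), 0.0)
    denom = Fb - Fa
    if np.any(denom <= 0):
        raise ValueError("non-positive likelihood contribution in score")
    return (wb - wa) / denom


def score_contributions(null_fit: EPolrFit, data: CohortTable) -> ScoreVector:
    """Extract each subject's treatment-score contribution under the null."""
    if null_fit.include_treatment:
        raise ValueError("null_fit must be an intercept-only fit "
                         "(include_treatment=False)")
    if null_fit.n_obs != len(data):
        raise ValueError("fit and data sizes differ")
    spec = null_fit.spec
    D_hi, D_lo, hi_inf, lo_inf = _design_matrices(data, spec)
    c = _theta_to_c(null_fit.theta_hat, spec)
    hb = np.where(hi_inf, np.inf, D_hi @ c)
    ha = np.where(lo_inf, -np.inf, D_lo @ c)
    return ScoreVector(_scores_from_h(hb, ha))


def permutation_test(scores: ScoreVector, arm: np.ndarray, *,
                     n_perm: int = 10_000, seed: int = 0,
                     stratum: np.ndarray | None = None) -> PermutationResult:
    """Two-sided permutation test of the treated-arm score sum.

    The null distribution is generated by uniformly re-randomizing the arm
    labels (group sizes preserved); with ``stratum`` given, labels are
    shuffled within strata instead.  The statistic is centered at its exact
    conditional mean (treated-group size times the mean score) and the
    p-value uses the add-one estimator ``(b + 1) / (n_perm + 1)``.
    """
    s = scores.scores
    arm = np.asarray(arm, dtype=int)
    if len(arm) != len(s):
        raise ValueError("scores and arm lengths differ")
    if arm.min() == arm.max():
        raise ValueError("both arms must be nonempty")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value",
                      UserWarning, stacklevel=2)

    rng = np.random.default_rng(seed)
    T = float(s[arm == 1].sum())

    # exact conditional mean of T under label exchange: n_treated * mean(S)
    # (summed per stratum for within-stratum shuffles)
    if stratum is None:
        perm_idx = np.argsort(rng.random((n_perm, len(s))), axis=1)
        perm_T = (s[perm_idx] * arm[None, :]).sum(axis=1)
        mean = float(arm.sum() * s.mean())
    else:
        stratum = np.asarray(stratum, dtype=object)
        perm_T = np.zeros(n_perm)
        mean = 0.0
        for lv in np.unique(stratum):
            mask = stratum == lv
            ss, aa = s[mask], arm[mask]
            idx = np.argsort(rng.random((n_perm, mask.sum())), axis=1)
            perm_T += (ss[idx] * aa[None, :]).sum(axis=1)
            mean += float(aa.sum() * ss.mean())

    sd = float(perm_T.std())
    obs_dev = abs(T - mean)
    # tolerance absorbs float noise so exact ties count as extreme
    tol = 1e-12 * (1.0 + abs(T) + abs(mean))
    b = int(np.sum(np.abs(perm_T - mean) >= obs_dev - tol))
    p = (b + 1) / (n_perm + 1)
    z = 0.0 if sd == 0 else (T - mean) / sd
    return PermutationResult(observed_T=T, z=float(z), p_value=float(p),
                             n_perm=n_perm, seed=seed)


def wilcoxon_score_transform(y: np.ndarray) -> ScoreVector:
    """Score contributions under the fixed rank-based transformation
    ``h(y_i) = logit(R_i / N)`` with upranks ``R_i = #{j : y_j <= y_i}``.

    For tie-free data this reduces to ``S_i = 1 - (2 R_i - 1) / N`` — the
    Wilcoxon scores up to an affine map — so the permutation test on these
    scores is the Wilcoxon rank-sum test.  Used for equivalence testing, not
    for analysis.
    """
    y = np.asarray(y, dtype=float)
    N = len(y)
    ub = np.array([(y <= v).sum() for v in y]) / N     # uprank / N
    ua = np.array([(y < v).sum() for v in y]) / N
    with np.errstate(divide="ignore"):
        hb = np.where(ub >= 1.0, np.inf, np.log(ub / (1 - ub)))
        ha = np.where(ua <= 0.0, -np.inf, np.log(ua / (1 - ua)))
    return ScoreVector(_scores_from_h(hb, ha), source="wilcoxon-rank-transform")
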