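"""Baseline-adjusted proportional odds model: likelihood, fitting, inference.

The model for an ordinal follow-up score ``Y`` on ``{0, ..., k_max}`` is

    P(Y <= y | baseline, stratum, x) = expit( h(y | baseline, stratum) + beta * x )

with ``x`` the treatment indicator (0 control, 1 treated) and ``h`` the
smooth monotone transformation of :mod:`epolr.transform`.  ``exp(beta)`` is
the odds ratio of scoring at-or-below any cut-off, treated versus control
(so ``exp(-beta)`` is the odds ratio on the benefit scale: values above 1
mean stochastically larger outcomes under treatment).

Estimation is joint maximum likelihood over ``(theta, beta)``.  Monotonicity
of ``h`` is enforced by parameterizing each stratum's implied Bernstein
coefficient vector as (first value, increments) with the increments kept
positive by box constraints, so a projected quasi-Newton solver with
analytic gradients handles the constrained problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit
from scipy.stats import binom as _binom
from scipy.stats import norm

from .transform import (
    MONOTONE_EPS,
    TransformationSpec,
    theta_as_blocks,
)

__all__ = [
    "CohortTable",
    "EPolrFit",
    "WaldSummary",
    "likelihood_contribution",
    "log_likelihood",
    "fit",
    "predict_distribution",
    "wald_inference",
]


# --------------------------------------------------------------------------
# data container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortTable:
    """Per-subject trial records: baseline score, follow-up score, stratum,
    and binary treatment arm."""

    baseline: np.ndarray
    outcome: np.ndarray
    stratum: np.ndarray
    arm: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.baseline, dtype=float)
        y = np.asarray(self.outcome)
        s = np.asarray(self.stratum, dtype=object)
        x = np.asarray(self.arm)
        n = len(y)
        if not (len(b) == len(s) == len(x) == n):
            raise ValueError("column lengths differ")
        if n == 0:
            raise ValueError("empty cohort")
        if np.any(pd.isna(b)) or np.any(pd.isna(y)) or np.any(pd.isna(x)):
            raise ValueError("missing values in analysis columns")
        if not np.all(np.asarray(y, dtype=float) == np.asarray(y, dtype=float).astype(int)):
            raise ValueError("outcome scores must be integers")
        if not np.all(np.isin(np.asarray(x, dtype=int), [0, 1])):
            raise ValueError("arm must be binary 0/1")
        object.__setattr__(self, "baseline", b)
        object.__setattr__(self, "outcome", np.asarray(y, dtype=float).astype(int))
        object.__setattr__(self, "stratum", s)
        object.__setattr__(self, "arm", np.asarray(x, dtype=int))

    def __len__(self) -> int:
        return len(self.outcome)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, outcome: str, baseline: str,
                   arm: str, stratum: Optional[str] = None) -> "CohortTable":
        s = (df[stratum].to_numpy(dtype=object) if stratum is not None
             else np.array(["all"] * len(df), dtype=object))
        return cls(
            baseline=df[baseline].to_numpy(),
            outcome=df[outcome].to_numpy(),
            stratum=s,
            arm=df[arm].to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "baseline": self.baseline,
            "outcome": self.outcome,
            "stratum": self.stratum,
            "arm": self.arm,
        })

    def with_outcome(self, outcome: np.ndarray) -> "CohortTable":
        return CohortTable(self.baseline, outcome, self.stratum, self.arm)

    def with_arm(self, arm: np.ndarray) -> "CohortTable":
        return CohortTable(self.baseline, self.outcome, self.stratum, arm)


# --------------------------------------------------------------------------
# internal design: natural coefficients c and the monotone reparameterization
# --------------------------------------------------------------------------
#
# Per stratum s the transformation is
#     h(y | m, s) = a(y)' c0_s * (1 - m) + a(y)' c1_s * m
# with m the baseline score scaled to [0, 1]; c0_s and c1_s are the implied
# Bernstein coefficient vectors at the extremes of the baseline range (c1_s
# is absent without a response-varying baseline effect).  h is monotone for
# every admissible baseline iff every c-block is increasing, which the
# (first value, log-increment) reparameterization guarantees.

def _n_blocks(spec: TransformationSpec) -> int:
    return spec.n_strata * (2 if spec.baseline_varying else 1)


def _bernstein_matrix(y: np.ndarray, spec: TransformationSpec) -> np.ndarray:
    """Rows of Bernstein basis values at integer points ``y`` (N x P)."""
    t = np.clip(np.asarray(y, dtype=float) / spec.scale.k_max, 0.0, 1.0)
    return _binom.pmf(np.arange(spec.n_params), spec.basis.degree, t[:, None])


def _design_matrices(data: CohortTable, spec: TransformationSpec):
    """Dense design matrices for h(y) and h(y-1) in c-coordinates, plus
    boundary masks."""
    y = data.outcome
    k = spec.scale.k_max
    P = spec.n_params
    nb = _n_blocks(spec)
    n = len(data)

    hi_inf = y >= k          # h(y) = +inf
    lo_inf = y <= 0          # h(y-1) = -inf

    A_hi = np.zeros((n, P))
    A_lo = np.zeros((n, P))
    A_hi[~hi_inf] = _bernstein_matrix(y[~hi_inf], spec)
    A_lo[~lo_inf] = _bernstein_matrix(y[~lo_inf] - 1, spec)

    s_idx = np.array([spec.stratum_index(s) for s in data.stratum])
    if spec.baseline_varying:
        m = np.clip(spec.scale_baseline(data.baseline), 0.0, 1.0)
        w = np.stack([1.0 - m, m], axis=1)      # (n, 2)
    else:
        w = np.ones((n, 1))

    D_hi = np.zeros((n, nb * P))
    D_lo = np.zeros((n, nb * P))
    ne = w.shape[1]
    for e in range(ne):
        block = (s_idx * ne + e)[:, None] * P + np.arange(P)[None, :]
        np.put_along_axis(D_hi, block, A_hi * w[:, [e]], axis=1)
        np.put_along_axis(D_lo, block, A_lo * w[:, [e]], axis=1)
    return D_hi, D_lo, hi_inf, lo_inf


def _decode_blocks(params: np.ndarray, P: int, nb: int):
    """Map block parameters (first value, increments d_1..d_{P-1}) per block
    to the increasing coefficient vector c, concatenated over blocks.

    The increments are kept >= MONOTONE_EPS by box constraints in the
    optimizer, so the map itself is linear and well-conditioned."""
    blk = params.reshape(nb, P)
    c = np.empty((nb, P))
    c[:, 0] = 0.0
    np.cumsum(blk[:, 1:], axis=1, out=c[:, 1:])
    c += blk[:, :1]
    return c.ravel()


def _decode_jacobian_chain(grad_c: np.ndarray, params: np.ndarray,
                           P: int, nb: int) -> np.ndarray:
    """Chain a gradient w.r.t. c back to the (u, d) block parameters."""
    gc = grad_c.reshape(nb, P)
    g = np.empty((nb, P))
    g[:, 0] = gc.sum(axis=1)
    # c_p depends on d_j for p >= j: reverse cumulative sum
    g[:, 1:] = np.cumsum(gc[:, ::-1], axis=1)[:, ::-1][:, 1:]
    return g.ravel()


def _encode_blocks(c: np.ndarray, P: int, nb: int) -> np.ndarray:
    cb = c.reshape(nb, P)
    params = np.empty((nb, P))
    params[:, 0] = cb[:, 0]
    params[:, 1:] = np.maximum(np.diff(cb, axis=1), MONOTONE_EPS)
    return params.ravel()


def _block_bounds(P: int, nb: int, include_treatment: bool):
    bounds = []
    if include_treatment:
        bounds.append((None, None))
    for _ in range(nb):
        bounds.append((None, None))                  # first coefficient
        bounds.extend([(MONOTONE_EPS, None)] * (P - 1))   # increments
    return bounds


def _c_to_theta(c: np.ndarray, spec: TransformationSpec) -> np.ndarray:
    """Map block coefficients c to the flat (P, S, C) theta layout."""
    P, S = spec.n_params, spec.n_strata
    theta = np.empty((P, S, spec.n_covariates))
    if spec.baseline_varying:
        cc = c.reshape(S, 2, P)
        theta[:, :, 0] = cc[:, 0, :].T
        theta[:, :, 1] = (cc[:, 1, :] - cc[:, 0, :]).T
    else:
        theta[:, :, 0] = c.reshape(S, P).T
    return theta.ravel()


def _theta_to_c(theta: np.ndarray, spec: TransformationSpec) -> np.ndarray:
    blocks = theta_as_blocks(theta, spec)     # (P, S, C)
    S, P = spec.n_strata, spec.n_params
    if spec.baseline_varying:
        c = np.empty((S, 2, P))
        c[:, 0, :] = blocks[:, :, 0].T
        c[:, 1, :] = (blocks[:, :, 0] + blocks[:, :, 1]).T
        return c.ravel()
    return blocks[:, :, 0].T.ravel()


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

def _log1mexp(d: np.ndarray) -> np.ndarray:
    """log(1 - exp(d)) for d < 0, numerically stable near both ends."""
    d = np.asarray(d, dtype=float)
    out = np.empty_like(d)
    small = d > -np.log(2.0)
    with np.errstate(divide="ignore"):
        out[small] = np.log(-np.expm1(d[small]))
        out[~small] = np.log1p(-np.exp(d[~small]))
    return out


def _log_prob(eta_b, eta_a, hi_inf, lo_inf):
    """log[ expit(eta_b) - expit(eta_a) ] with +-inf boundary conventions."""
    lp = np.empty_like(eta_b)
    both = ~hi_inf & ~lo_inf
    lp[both] = (log_expit(eta_b[both]) + log_expit(-eta_a[both])
                + _log1mexp(eta_a[both] - eta_b[both]))
    lp[hi_inf] = log_expit(-eta_a[hi_inf])
    lp[lo_inf & ~hi_inf] = log_expit(eta_b[lo_inf & ~hi_inf])
    return lp


def likelihood_contribution(y: int, baseline: float, stratum, x: int,
                            theta: np.ndarray, beta: float,
                            spec: TransformationSpec) -> float:
    """Probability ``P(Y = y | baseline, stratum, x)`` under the model."""
    theta = np.asarray(theta, dtype=float).ravel()
    if not np.all(np.isfinite(theta)) or not np.isfinite(beta):
        raise ValueError("non-finite parameters")
    from .transform import eval_h
    hb = eval_h(y, stratum, baseline, theta, spec)
    ha = eval_h(y - 1, stratum, baseline, theta, spec)
    eta_b = np.atleast_1d(hb + beta * x if np.isfinite(hb) else np.inf)
    eta_a = np.atleast_1d(ha + beta * x if np.isfinite(ha) else -np.inf)
    lp = _log_prob(eta_b, eta_a,
                   np.atleast_1d(~np.isfinite(hb) & (hb > 0)),
                   np.atleast_1d(~np.isfinite(ha) & (ha < 0)))
    return float(np.exp(lp[0]))


def log_likelihood(data: CohortTable, theta: np.ndarray, beta: float,
                   spec: TransformationSpec) -> float:
    """Sum of log likelihood contributions over the cohort."""
    D_hi, D_lo, hi_inf, lo_inf = _design_matrices(data, spec)
    c = _theta_to_c(np.asarray(theta, dtype=float).ravel(), spec)
    off = beta * data.arm
    eta_b = np.where(hi_inf, np.inf, D_hi @ c + off)
    eta_a = np.where(lo_inf, -np.inf, D_lo @ c + off)
    return float(np.sum(_log_prob(eta_b, eta_a, hi_inf, lo_inf)))


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class WaldSummary:
    """Wald inference for the treatment effect, reported on both odds-ratio
    directions.

    ``or_lte`` is exp(beta): the odds of scoring lower-or-equal, treated
    versus control.  ``or_benefit`` is exp(-beta): values above 1 mean the
    treatment shifts outcomes upward.
    """
    beta: float
    se: float
    z: float
    p_value: float
    level: float
    or_lte: float
    or_lte_ci: tuple
    or_benefit: float
    or_benefit_ci: tuple
    direction: str = "or_lte = odds of Y<=y treated:control; or_benefit = exp(-beta)"

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["or_lte_ci"] = list(self.or_lte_ci)
        d["or_benefit_ci"] = list(self.or_benefit_ci)
        return d


@dataclass
class EPolrFit:
    """Result of a maximum-likelihood fit."""

    beta_hat: float
    theta_hat: np.ndarray          # flat, (P*S*C,)
    loglik: float
    converged: bool
    spec: TransformationSpec
    n_obs: int
    include_treatment: bool
    message: str = ""
    vcov: Optional[np.ndarray] = None   # natural scale, beta first (if fitted)
    beta_se: Optional[float] = None
    _reparam: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def theta_blocks(self) -> np.ndarray:
        return theta_as_blocks(self.theta_hat, self.spec)


def _check_identifiability(data: CohortTable, spec: TransformationSpec) -> None:
    for s in np.unique(data.stratum):
        spec.stratum_index(s)  # raises on unknown labels
        mask = data.stratum == s
        ys = np.unique(data.outcome[mask])
        if len(ys) < 2:
            raise ValueError(
                f"stratum {s!r} has fewer than 2 distinct outcome values; "
                "the transformation is unidentifiable there"
            )
        if mask.sum() < spec.n_params:
            warnings.warn(
                f"stratum {s!r} has {mask.sum()} observations, fewer than "
                f"the {spec.n_params} basis parameters", UserWarning,
                stacklevel=3,
            )


def _initial_c(data: CohortTable, spec: TransformationSpec) -> np.ndarray:
    """Initialize each stratum's coefficients from the empirical marginal
    logit-CDF on the Bernstein grid (zero baseline slope)."""
    P = spec.n_params
    k = spec.scale.k_max
    grid = np.linspace(0, k, P)
    ne = 2 if spec.baseline_varying else 1
    c = np.empty((spec.n_strata, ne, P))
    for si, s in enumerate(spec.strata_levels):
        mask = data.stratum == s
        y = data.outcome[mask] if mask.any() else data.outcome
        n = len(y)
        F = np.array([(y <= g).mean() for g in grid])
        F = np.clip(F, 1.0 / (2 * n + 2), 1 - 1.0 / (2 * n + 2))
        c0 = np.log(F / (1 - F))
        for p in range(1, P):    # enforce strict increase
            c0[p] = max(c0[p], c0[p - 1] + 1e-3)
        c[si] = c0
    return c.ravel()


def _nll_and_grad(params, D_hi, D_lo, hi_inf, lo_inf, arm, P, nb,
                  include_treatment):
    if include_treatment:
        beta, bp = params[0], params[1:]
    else:
        beta, bp = 0.0, params
    c = _decode_blocks(bp, P, nb)
    off = beta * arm
    eta_b = np.where(hi_inf, np.inf, D_hi @ c + off)
    eta_a = np.where(lo_inf, -np.inf, D_lo @ c + off)
    lp = _log_prob(eta_b, eta_a, hi_inf, lo_inf)
    nll = -float(np.sum(lp))

    # gradient of each lp w.r.t. eta_b and eta_a
    p = np.exp(np.maximum(lp, -700.0))
    w_b = np.zeros_like(lp)
    w_a = np.zeros_like(lp)
    fb = ~hi_inf
    fa = ~lo_inf
    both = fb & fa
    w_b[both] = expit(eta_b[both]) * expit(-eta_b[both]) / p[both]
    w_a[both] = -expit(eta_a[both]) * expit(-eta_a[both]) / p[both]
    w_b[lo_inf & fb] = expit(-eta_b[lo_inf & fb])
    w_a[hi_inf & fa] = -expit(eta_a[hi_inf & fa])

    grad_c = D_hi.T @ w_b + D_lo.T @ w_a
    grad_bp = _decode_jacobian_chain(grad_c, bp, P, nb)
    if include_treatment:
        gbeta = float(np.sum(arm * (w_b + w_a)))
        return nll, -np.concatenate(([gbeta], grad_bp))
    return nll, -grad_bp


def _natural_params(params, spec, include_treatment):
    """Map the unconstrained parameter vector to (beta, theta_flat)."""
    P, nb = spec.n_params, _n_blocks(spec)
    if include_treatment:
        beta, bp = params[0], params[1:]
    else:
        beta, bp = 0.0, params
    theta = _c_to_theta(_decode_blocks(bp, P, nb), spec)
    return np.concatenate(([beta], theta))


def _fd_hessian(fun_grad, x0, args, h=1e-5):
    d = len(x0)
    H = np.empty((d, d))
    for j in range(d):
        xp = x0.copy(); xp[j] += h
        xm = x0.copy(); xm[j] -= h
        gp = fun_grad(xp, *args)[1]
        gm = fun_grad(xm, *args)[1]
        H[:, j] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _fd_jacobian(fun, x0, h=1e-6):
    f0 = fun(x0)
    J = np.empty((len(f0), len(x0)))
    for j in range(len(x0)):
        xp = x0.copy(); xp[j] += h
        xm = x0.copy(); xm[j] -= h
        J[:, j] = (fun(xp) - fun(xm)) / (2 * h)
    return J


def fit(data: CohortTable, spec: TransformationSpec, *,
        include_treatment: bool = True,
        compute_vcov: Optional[bool] = None,
        gtol: float = 1e-8, maxiter: int = 1000) -> EPolrFit:
    """Maximize the log-likelihood subject to monotonicity of ``h``.

    With ``include_treatment=False`` the treatment coefficient is fixed at 0
    (the intercept-only model used as the permutation-test null and as the
    simulation generator).  The covariance of the estimates is the inverse
    observed information (numerical Hessian of the reparameterized objective,
    delta-method back-transform to the natural scale).
    """
    if compute_vcov is None:
        compute_vcov = include_treatment
    _check_identifiability(data, spec)

    P, nb = spec.n_params, _n_blocks(spec)
    D_hi, D_lo, hi_inf, lo_inf = _design_matrices(data, spec)
    arm = data.arm.astype(float)
    args = (D_hi, D_lo, hi_inf, lo_inf, arm, P, nb, include_treatment)

    x0 = _encode_blocks(_initial_c(data, spec), P, nb)
    if include_treatment:
        x0 = np.concatenate(([0.0], x0))

    bounds = _block_bounds(P, nb, include_treatment)
    opts = {"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12, "maxcor": 40}
    res = optimize.minimize(
        _nll_and_grad, x0, args=args, jac=True, method="L-BFGS-B",
        bounds=bounds, options=opts,
    )
    # one restart with fresh curvature memory: the likelihood has long
    # shallow valleys in weakly identified transformation directions, and a
    # restart reliably escapes premature line-search termination there
    res2 = optimize.minimize(
        _nll_and_grad, res.x, args=args, jac=True, method="L-BFGS-B",
        bounds=bounds, options=opts,
    )
    if res2.fun <= res.fun:
        res = res2
    converged = bool(res.success)
    if not res.success:
        warnings.warn(f"optimizer did not report convergence: {res.message}",
                      UserWarning, stacklevel=2)

    nat = _natural_params(res.x, spec, include_treatment)
    beta_hat, theta_hat = float(nat[0]), nat[1:]

    vcov = None
    beta_se = None
    if compute_vcov:
        H = _fd_hessian(_nll_and_grad, res.x, args)
        Vrep = np.linalg.pinv(H, hermitian=True)
        J = _fd_jacobian(lambda x: _natural_params(x, spec, include_treatment),
                         res.x)
        if not include_treatment:
            # beta fixed: natural beta row of J is zero, vcov row/col zero
            pass
        vcov = J @ Vrep @ J.T
        var_beta = vcov[0, 0]
        if include_treatment:
            if var_beta <= 0:
                warnings.warn("non-positive variance estimate for beta",
                              UserWarning, stacklevel=2)
            else:
                beta_se = float(np.sqrt(var_beta))

    return EPolrFit(
        beta_hat=beta_hat, theta_hat=theta_hat,
        loglik=-float(res.fun), converged=converged, spec=spec,
        n_obs=len(data), include_treatment=include_treatment,
        message=str(res.message), vcov=vcov, beta_se=beta_se,
        _reparam=res.x,
    )


# --------------------------------------------------------------------------
# prediction and Wald inference
# --------------------------------------------------------------------------

def _h_grid(fit_or_theta, spec, baseline, stratum) -> np.ndarray:
    """h(y) for y = 0..k_max-1, vectorized over subjects: returns (n, k)."""
    theta = (fit_or_theta.theta_hat
             if isinstance(fit_or_theta, EPolrFit) else fit_or_theta)
    c = _theta_to_c(theta, spec).reshape(-1, spec.n_params)   # (nb, P)
    A = _bernstein_matrix(np.arange(spec.scale.k_max), spec)  # (k, P)
    Hb = A @ c.T                                              # (k, nb)
    s_idx = np.array([spec.stratum_index(s) for s in np.atleast_1d(
        np.asarray(stratum, dtype=object))])
    if spec.baseline_varying:
        m = np.clip(np.atleast_1d(spec.scale_baseline(baseline)), 0.0, 1.0)
        return ((1.0 - m)[:, None] * Hb[:, 2 * s_idx].T
                + m[:, None] * Hb[:, 2 * s_idx + 1].T)
    return Hb[:, s_idx].T


def _h_values(fit_or_theta, spec, baseline, stratum) -> np.ndarray:
    """h(y) for y = 0..k_max-1 at one covariate combination."""
    return _h_grid(fit_or_theta, spec, [baseline], [stratum])[0]


def predict_distribution(fit: EPolrFit, baseline: float, stratum,
                         x: int) -> np.ndarray:
    """Conditional PMF over ``{0, ..., k_max}`` for one covariate setting."""
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to predict")
    h = _h_values(fit, fit.spec, baseline, stratum)
    cdf = np.append(expit(h + fit.beta_hat * x), 1.0)
    pmf = np.diff(np.concatenate(([0.0], cdf)))
    return np.clip(pmf, 0.0, 1.0)


def wald_inference(fit: EPolrFit, level: float = 0.95) -> WaldSummary:
    """Asymptotic-normal test and CI for the treatment log-odds ratio."""
    if not fit.include_treatment:
        raise ValueError("fit has no treatment coefficient")
    if fit.beta_se is None or fit.beta_se <= 0:
        raise ValueError("no positive variance estimate available")
    b, se = fit.beta_hat, fit.beta_se
    zq = norm.ppf(1 - (1 - level) / 2)
    z = b / se
    p = 2 * norm.sf(abs(z))
    lo, hi = np.exp(b - zq * se), np.exp(b + zq * se)
    return WaldSummary(
        beta=b, se=se, z=z, p_value=float(p), level=level,
        or_lte=float(np.exp(b)), or_lte_ci=(float(lo), float(hi)),
        or_benefit=float(np.exp(-b)),
        or_benefit_ci=(float(1 / hi), float(1 / lo)),
    )
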