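"""Monotone smooth transformation functions for ordinal outcomes.

The baseline log-odds function ``h(y | baseline, stratum)`` of a proportional
odds model with many outcome categories is parameterized here by a Bernstein
polynomial in the (floored) outcome, tensored with a dummy coding of strata
and a response-varying baseline covariate.  With ``P`` basis functions,
``S`` strata and ``C`` covariates (default: intercept and the baseline score)
the transformation has ``P * S * C`` parameters; monotonicity in ``y`` is a
linear constraint on each stratum's implied Bernstein coefficient vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

__all__ = [
    "OrdinalScale",
    "BernsteinBasis",
    "TransformationSpec",
    "bernstein_row",
    "floor_discretize",
    "design_row",
    "eval_h",
    "monotonicity_constraints",
]

#: minimum spacing between adjacent constrained coefficients
MONOTONE_EPS = 1e-8


@dataclass(frozen=True)
class OrdinalScale:
    """Integer outcome support ``{0, ..., k_max}``.

    The transformation uses the boundary conventions ``h(-1) = -inf`` and
    ``h(k_max) = +inf`` so that the cumulative distribution function is 0
    below the support and 1 at its top.
    """

    k_max: int

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError(f"k_max must be >= 1, got {self.k_max}")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.k_max + 1)


@dataclass(frozen=True)
class BernsteinBasis:
    """Bernstein polynomial basis of ``n_params`` functions (degree P-1)
    on the interval ``[lo, hi]``."""

    n_params: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.n_params < 2:
            raise ValueError("Bernstein basis needs at least 2 functions")
        if not self.lo < self.hi:
            raise ValueError(f"invalid interval [{self.lo}, {self.hi}]")

    @property
    def degree(self) -> int:
        return self.n_params - 1


def bernstein_row(y: float, basis: BernsteinBasis) -> np.ndarray:
    """Evaluate the ``P`` Bernstein basis functions at ``y``.

    The point is affinely mapped to ``t = (y - lo) / (hi - lo)`` and the
    basis values are the Binomial(P-1, t) probabilities — non-negative and
    summing to one (partition of unity).
    """
    if not (basis.lo <= y <= basis.hi):
        raise ValueError(
            f"y={y} outside the basis interval [{basis.lo}, {basis.hi}]"
        )
    t = (y - basis.lo) / (basis.hi - basis.lo)
    return binom.pmf(np.arange(basis.n_params), basis.degree, t)


def floor_discretize(y: float) -> int:
    """Largest integer <= y; applied before basis evaluation so h is a
    right-continuous step function of an underlying real argument."""
    return int(math.floor(y))


@dataclass(frozen=True)
class TransformationSpec:
    """Stratified, response-varying Bernstein parameterization of ``h``.

    Parameters are laid out as ``theta[p, s, c]`` with ``p`` indexing basis
    functions, ``s`` strata and ``c`` covariates.  The flattened design row
    for an observation is the Kronecker product
    ``bernstein_row(floor(y)) (x) stratum_dummy (x) covariates`` where the
    covariate vector is ``(1,)`` or ``(1, baseline_scaled)``; the baseline
    score is internally rescaled to [0, 1] by its declared range.
    """

    scale: OrdinalScale
    strata_levels: tuple
    n_params: int = 7
    baseline_varying: bool = True
    baseline_range: tuple[float, float] = (0.0, 1.0)
    basis: BernsteinBasis = field(init=False)

    def __post_init__(self) -> None:
        if len(self.strata_levels) != len(set(self.strata_levels)):
            raise ValueError("duplicate stratum labels")
        if self.baseline_varying and not (
            self.baseline_range[0] < self.baseline_range[1]
        ):
            raise ValueError("baseline_range must be a nondegenerate interval")
        object.__setattr__(
            self,
            "basis",
            BernsteinBasis(self.n_params, 0.0, float(self.scale.k_max)),
        )

    @property
    def n_strata(self) -> int:
        return len(self.strata_levels)

    @property
    def n_covariates(self) -> int:
        return 2 if self.baseline_varying else 1

    @property
    def n_theta(self) -> int:
        """Total transformation parameter count P * S * C."""
        return self.n_params * self.n_strata * self.n_covariates

    def stratum_index(self, stratum) -> int:
        try:
            return self.strata_levels.index(stratum)
        except ValueError:
            raise KeyError(
                f"unknown stratum {stratum!r}; declared: {self.strata_levels}"
            ) from None

    def scale_baseline(self, baseline) -> np.ndarray:
        """Rescale the baseline score to [0, 1] by its theoretical range."""
        lo, hi = self.baseline_range
        return (np.asarray(baseline, dtype=float) - lo) / (hi - lo)

    def covariate_vector(self, baseline: float) -> np.ndarray:
        if self.baseline_varying:
            return np.array([1.0, float(self.scale_baseline(baseline))])
        return np.array([1.0])

    @classmethod
    def from_config(cls, config: dict) -> "TransformationSpec":
        """Build a spec from a plain mapping, e.g. parsed YAML/JSON:
        ``{order: 7, strata: [...], k_max: 50, baseline_range: [0, 28]}``."""
        baseline_range = config.get("baseline_range")
        return cls(
            scale=OrdinalScale(int(config["k_max"])),
            strata_levels=tuple(config.get("strata", ("all",))),
            n_params=int(config.get("order", 7)),
            baseline_varying=baseline_range is not None,
            baseline_range=(
                tuple(float(v) for v in baseline_range)
                if baseline_range is not None
                else (0.0, 1.0)
            ),
        )

    def to_config(self) -> dict:
        cfg = {
            "k_max": self.scale.k_max,
            "strata": list(self.strata_levels),
            "order": self.n_params,
        }
        if self.baseline_varying:
            cfg["baseline_range"] = list(self.baseline_range)
        return cfg


def design_row(
    y: int, stratum, baseline: float, spec: TransformationSpec
) -> np.ndarray:
    """Flattened design row ``a(floor(y)) (x) stratum_dummy (x) covariates``.

    Entries outside the observation's stratum block are zero; the row length
    equals ``spec.n_theta``.
    """
    a = bernstein_row(floor_discretize(y), spec.basis)
    dummy = np.zeros(spec.n_strata)
    dummy[spec.stratum_index(stratum)] = 1.0
    return np.kron(a, np.kron(dummy, spec.covariate_vector(baseline)))


def eval_h(
    y: int,
    stratum,
    baseline: float,
    theta: np.ndarray,
    spec: TransformationSpec,
) -> float:
    """Evaluate ``h(y | baseline, stratum)`` with boundary conventions
    ``h(-1) = -inf`` and ``h(k_max) = +inf``."""
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size != spec.n_theta:
        raise ValueError(
            f"theta has {theta.size} entries, spec declares {spec.n_theta}"
        )
    if y <= -1:
        return -math.inf
    if y >= spec.scale.k_max:
        return math.inf
    return float(design_row(y, stratum, baseline, spec) @ theta)


def theta_as_blocks(theta: np.ndarray, spec: TransformationSpec) -> np.ndarray:
    """Reshape a flat theta to the ``(P, S, C)`` layout."""
    return np.asarray(theta, dtype=float).reshape(
        spec.n_params, spec.n_strata, spec.n_covariates
    )


def implied_coefficients(
    theta: np.ndarray, spec: TransformationSpec
) -> np.ndarray:
    """Bernstein coefficient vectors of the implied polynomial at the two
    extremes of the scaled baseline range, per stratum.

    Returns an array of shape ``(S, n_extremes, P)`` where ``n_extremes`` is
    1 without a response-varying baseline effect and 2 with one.  ``h`` is
    affine in the scaled baseline, so it is non-decreasing in ``y`` for every
    admissible baseline iff each of these coefficient vectors is increasing.
    """
    blocks = theta_as_blocks(theta, spec)  # (P, S, C)
    if spec.baseline_varying:
        at0 = blocks[:, :, 0]
        at1 = blocks[:, :, 0] + blocks[:, :, 1]
        return np.stack([at0.T, at1.T], axis=1)  # (S, 2, P)
    return blocks[:, :, 0].T[:, None, :]  # (S, 1, P)


def monotonicity_constraints(spec: TransformationSpec) -> dict:
    """Describe the linear inequalities that make ``h`` non-decreasing.

    For each stratum, the implied Bernstein coefficients must increase:
    ``c_1 < c_2 < ... < c_P``, enforced at both extremes of the baseline
    range when the baseline effect is response-varying.  Returns a mapping
    with the inequality count and a ``check(theta)`` predicate.
    """
    n_extremes = 2 if spec.baseline_varying else 1
    n_ineq = (spec.n_params - 1) * spec.n_strata * n_extremes

    def check(theta: np.ndarray) -> bool:
        coefs = implied_coefficients(theta, spec)
        return bool(np.all(np.diff(coefs, axis=-1) > 0))

    return {
        "n_inequalities": n_ineq,
        "per_block": spec.n_params - 1,
        "n_blocks": spec.n_strata * n_extremes,
        "check": check,
        "description": (
            "increasing Bernstein coefficients per stratum, evaluated at "
            "the extremes of the scaled baseline range"
        ),
    }
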