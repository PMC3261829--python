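"""Parametric opinion model: constrained Beta fits, pooling, opinion mapping.

Each expert's elicited distribution over the transformed effectiveness
scale is modelled as a Beta(alpha, beta) density with both shapes
constrained to be >= 1, so the fitted distribution is unimodal (or, at the
corner alpha = beta = 1, uniform — total ignorance).  A panel is combined
by multiplicative (normalised geometric-mean) pooling, which for Beta
members has an exact parametric form: the pooled density is again Beta with
the arithmetic means of the member shape parameters.  The pooled shapes map
onto a subjective-logic opinion triplet

    b = (alpha - 1) / (alpha + beta - 1)        belief
    d = (beta - 1) / (alpha + beta - 1)         disbelief
    u = 1 / (alpha + beta - 1)                  uncertainty

with b + d + u = 1.  Larger alpha relative to beta means more belief; the
uniform density (1, 1) maps to pure uncertainty {0, 0, 1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .assessments import Assessment, RatingScale

__all__ = [
    "Opinion",
    "BetaFit",
    "PooledBeta",
    "DegenerateAssessmentError",
    "FitError",
    "fit_beta",
    "fit_case",
    "pool_beta",
    "opinion_from_beta",
    "beta_moments",
]

#: Numerical guard on the shape parameters.  A fit pinned at this bound
#: signals a near-degenerate assessment (nearly all weight in one category).
SHAPE_MAX = 1000.0

_SUM_TOL = 1e-12


class DegenerateAssessmentError(ValueError):
    """Raised when an assessment concentrates all weight in one category.

    A point mass has no finite maximum-likelihood Beta shapes and its
    opinion would have u = 0, which breaks pooling semantics.
    """


class FitError(RuntimeError):
    """Raised when the likelihood optimiser fails to converge."""


@dataclass(frozen=True)
class Opinion:
    """A belief / disbelief / uncertainty triplet on the 2-simplex."""

    belief: float
    disbelief: float
    uncertainty: float

    def __post_init__(self) -> None:
        total = self.belief + self.disbelief + self.uncertainty
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"opinion components must sum to 1 (got {total!r})")
        for name in ("belief", "disbelief", "uncertainty"):
            v = getattr(self, name)
            if not -_SUM_TOL <= v <= 1 + _SUM_TOL:
                raise ValueError(f"{name} must lie in [0, 1] (got {v!r})")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.belief, self.disbelief, self.uncertainty)

    def to_dict(self) -> dict[str, float]:
        return {"b": self.belief, "d": self.disbelief, "u": self.uncertainty}

    def __iter__(self):
        return iter(self.as_tuple())


@dataclass(frozen=True)
class BetaFit:
    """Constrained maximum-likelihood Beta shapes for one assessment."""

    alpha: float
    beta: float
    loglik: float
    converged: bool = True
    at_bound: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        if self.alpha < 1 or self.beta < 1:
            raise ValueError("shape parameters must be >= 1 (unimodality)")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")


@dataclass(frozen=True)
class PooledBeta:
    """Multiplicatively pooled panel: arithmetic means of member shapes."""

    alpha_bar: float
    beta_bar: float
    n_members: int

    def __post_init__(self) -> None:
        if self.alpha_bar < 1 or self.beta_bar < 1:
            raise ValueError("pooled shapes must be >= 1")

    @property
    def mean(self) -> float:
        """Pooled mean effectiveness alpha / (alpha + beta)."""
        return self.alpha_bar / (self.alpha_bar + self.beta_bar)


def _neg_loglik(params: np.ndarray, midpoints: np.ndarray, probs: np.ndarray) -> float:
    alpha, beta = params
    return -float(probs @ stats.beta.logpdf(midpoints, alpha, beta))


def _moment_start(midpoints: np.ndarray, probs: np.ndarray) -> tuple[float, float]:
    mu = float(probs @ midpoints)
    var = float(probs @ (midpoints - mu) ** 2)
    # Method-of-moments shapes, clipped into the constraint box.
    common = mu * (1 - mu) / var - 1
    a0 = float(np.clip(mu * common, 1.0, SHAPE_MAX))
    b0 = float(np.clip((1 - mu) * common, 1.0, SHAPE_MAX))
    return a0, b0


def fit_beta(assessment: Assessment, scale: RatingScale) -> BetaFit:
    """Fit Beta(alpha, beta), alpha, beta >= 1, by weighted maximum likelihood.

    The objective is the weighted log-likelihood
    ``sum_k (w_k / 100) * log f(m_k; alpha, beta)`` over the category
    midpoints ``m_k`` — equivalent to ordinary MLE on a pseudo-sample of
    100 observations placed at the midpoints with the elicited percentages
    as multiplicities.

    Raises
    ------
    DegenerateAssessmentError
        If the assessment puts all weight in a single category.
    FitError
        If neither the box-constrained quasi-Newton search nor the
        Nelder-Mead fallback converges.
    """
    if assessment.is_degenerate(scale):
        raise DegenerateAssessmentError(
            f"assessment {assessment.case_id}/{assessment.expert_id} is a "
            "point mass; its maximum-likelihood Beta shapes diverge"
        )
    m = scale.midpoint_array
    p = assessment.probabilities
    x0 = _moment_start(m, p)
    res = optimize.minimize(
        _neg_loglik,
        x0,
        args=(m, p),
        method="L-BFGS-B",
        bounds=[(1.0, SHAPE_MAX), (1.0, SHAPE_MAX)],
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
    )
    if not res.success:
        # Nelder-Mead on log-shifted parameters, then project back into the box.
        def reparam(z: np.ndarray) -> np.ndarray:
            return 1.0 + np.exp(z)

        res_nm = optimize.minimize(
            lambda z: _neg_loglik(reparam(z), m, p),
            np.log(np.maximum(np.asarray(x0) - 1.0, 1e-8)),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        if not res_nm.success:
            raise FitError(
                f"Beta fit failed for {assessment.case_id}/{assessment.expert_id}: "
                f"{res.message} / {res_nm.message}"
            )
        params = np.clip(reparam(res_nm.x), 1.0, SHAPE_MAX)
        fun = _neg_loglik(params, m, p)
    else:
        params, fun = res.x, res.fun
    alpha, beta = float(params[0]), float(params[1])
    at_bound = (alpha >= SHAPE_MAX, beta >= SHAPE_MAX)
    if any(at_bound):
        warnings.warn(
            f"Beta fit for {assessment.case_id}/{assessment.expert_id} hit the "
            f"shape bound {SHAPE_MAX:g}; assessment is near-degenerate",
            UserWarning,
            stacklevel=2,
        )
    return BetaFit(alpha, beta, loglik=-float(fun), converged=True, at_bound=at_bound)


def fit_case(assessments: list[Assessment], scale: RatingScale) -> list[BetaFit]:
    """Fit every expert of one case."""
    return [fit_beta(a, scale) for a in assessments]


def pool_beta(fits: list[BetaFit] | list[tuple[float, float]]) -> PooledBeta:
    """Multiplicative (geometric-mean) pooling of Beta fits.

    The normalised geometric mean of Beta densities is itself Beta with
    shape parameters equal to the arithmetic means of the member shapes, so
    the pooled density is computed exactly rather than numerically.
    """
    if not fits:
        raise ValueError("cannot pool an empty panel")
    alphas = [f.alpha if isinstance(f, BetaFit) else f[0] for f in fits]
    betas = [f.beta if isinstance(f, BetaFit) else f[1] for f in fits]
    return PooledBeta(
        alpha_bar=float(np.mean(alphas)),
        beta_bar=float(np.mean(betas)),
        n_members=len(fits),
    )


def opinion_from_beta(alpha: float, beta: float) -> Opinion:
    """Map Beta shapes (alpha, beta >= 1) to a (b, d, u) opinion triplet."""
    if alpha < 1 or beta < 1:
        raise ValueError(
            "opinion mapping requires alpha >= 1 and beta >= 1 "
            f"(got alpha={alpha!r}, beta={beta!r})"
        )
    s = alpha + beta - 1.0
    return Opinion(
        belief=(alpha - 1.0) / s,
        disbelief=(beta - 1.0) / s,
        uncertainty=1.0 / s,
    )


def beta_moments(alpha: float, beta: float) -> tuple[float, float]:
    """Mean and variance of Beta(alpha, beta) in closed form."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("shape parameters must be positive")
    s = alpha + beta
    mean = alpha / s
    variance = alpha * beta / (s * s * (s + 1.0))
    return mean, variance
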