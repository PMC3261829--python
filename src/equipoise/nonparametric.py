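"""Distribution-free opinion model based on weighted moments.

The moment formulation needs no distributional assumption: for an
assessment with weighted mean ``mu`` and standard deviation ``sigma`` on
the transformed [0, 1] scale,

    u = sigma^2 / (mu * (1 - mu)),   b = mu * (1 - u),   d = (1 - mu) * (1 - u).

Because sigma^2 <= mu (1 - mu) for any distribution supported on [0, 1],
u always lies in [0, 1] and the triplet sums to one.  Multiplicative
pooling acts on the raw weight vectors: the pooled weight in category k is
the n-th root of the product of the experts' weights there, renormalised.
Zeros propagate — the pooled panel only supports categories every expert
gave some weight to (intersection-of-beliefs semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assessments import Assessment, RatingScale
from .beta_model import Opinion

__all__ = [
    "MomentSummary",
    "EmptyIntersectionError",
    "weighted_moments",
    "opinion_from_moments",
    "pool_nonparametric",
]


class EmptyIntersectionError(ValueError):
    """Raised when no category receives weight from every expert."""


@dataclass(frozen=True)
class MomentSummary:
    """Weighted mean and standard deviation of an assessment on [0, 1]."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mean must lie in [0, 1]")
        # Attainable variance bound for [0, 1]-supported distributions.
        if self.sigma**2 > self.mu * (1.0 - self.mu) + 1e-12:
            raise ValueError("sigma^2 exceeds mu (1 - mu): impossible on [0, 1]")


def _moments_of(probs: np.ndarray, midpoints: np.ndarray) -> MomentSummary:
    mu = float(probs @ midpoints)
    var = float(probs @ (midpoints - mu) ** 2)
    return MomentSummary(mu=mu, sigma=float(np.sqrt(max(var, 0.0))))


def weighted_moments(assessment: Assessment, scale: RatingScale) -> MomentSummary:
    """Population-weighted mean and SD of an assessment at the scale midpoints.

    The weights are a complete elicited distribution rather than a sample,
    so the population form (divisor = total weight) is used.
    """
    return _moments_of(assessment.probabilities, scale.midpoint_array)


def opinion_from_moments(moments: MomentSummary) -> Opinion:
    """Map (mu, sigma) to a (b, d, u) opinion triplet.

    Undefined for mu in {0, 1}: the uncertainty ratio has a vanishing
    denominator at the endpoints.
    """
    mu, sigma = moments.mu, moments.sigma
    if mu <= 0.0 or mu >= 1.0:
        raise ValueError("opinion mapping requires 0 < mu < 1")
    u = min(sigma**2 / (mu * (1.0 - mu)), 1.0)
    return Opinion(belief=mu * (1.0 - u), disbelief=(1.0 - mu) * (1.0 - u), uncertainty=u)


def pool_nonparametric(
    assessments: list[Assessment],
    scale: RatingScale,
    epsilon: float = 0.0,
) -> tuple[np.ndarray, Opinion]:
    """Geometric-mean pooling of raw weight vectors, then the moment opinion.

    Returns the pooled probability vector (summing to 1) and its opinion.
    ``epsilon`` optionally floors each weight before multiplication for
    exploratory use; by default zeros propagate, and a panel with no common
    category raises :class:`EmptyIntersectionError`.
    """
    if not assessments:
        raise ValueError("cannot pool an empty panel")
    w = np.vstack([a.weight_array for a in assessments])
    if epsilon > 0.0:
        w = np.maximum(w, epsilon)
    # Geometric mean per category via logs; zeros yield -inf -> 0.
    with np.errstate(divide="ignore"):
        pooled = np.exp(np.mean(np.log(w), axis=0))
    pooled[~np.isfinite(pooled)] = 0.0
    total = pooled.sum()
    if total == 0.0:
        raise EmptyIntersectionError(
            "no category is supported by every expert; multiplicative "
            "pooling of disjoint assessments is empty"
        )
    pooled /= total
    opinion = opinion_from_moments(_moments_of(pooled, scale.midpoint_array))
    return pooled, opinion
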