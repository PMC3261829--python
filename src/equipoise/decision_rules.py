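"""Decision rules partitioning the opinion space into recruitment regions.

Two rules are implemented.  The *80:20 rule* declares equipoise disturbed
once more than 80% of the pooled probability mass lies on one side of the
equipoise point e: with P = BetaCDF(e; alpha, beta), P < 0.2 is *belief*
(mass concentrated above e, intervention favoured), P > 0.8 is
*disbelief*, anything between is *equipoise*.  The *mean-threshold rule*
declares equipoise while the pooled mean effectiveness mu = alpha /
(alpha + beta) stays inside fixed bounds (0.4 and 0.7 by default); mu
above the upper bound is belief, below the lower bound disbelief.

Opinions landing exactly on a rule boundary are classed as equipoise — the
conservative choice for a test whose null hypothesis is that the patient
should not be recruited.

Both rules trace to one-dimensional boundaries in the ternary opinion
space: closed-form lines for the mean thresholds, root-found curves of
constant Beta CDF for the 80:20 split.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .assessments import parse_fraction
from .beta_model import Opinion, opinion_from_beta

__all__ = [
    "Region",
    "DecisionRule",
    "MeanBoundary",
    "eighty_twenty",
    "mean_threshold",
    "heel_trial_rule",
    "classify",
    "classify_80_20",
    "classify_mean_threshold",
    "trace_boundary_80_20",
    "trace_boundary_mean",
]

#: Ties within this distance of a rule boundary count as equipoise.
BOUNDARY_TOL = 1e-12

_BETA_MAX = 1000.0


class Region(str, enum.Enum):
    """Exhaustive three-way classification of an opinion."""

    BELIEF = "belief"
    EQUIPOISE = "equipoise"
    DISBELIEF = "disbelief"

    def __str__(self) -> str:  # clean JSON / CLI rendering
        return self.value


@dataclass(frozen=True)
class DecisionRule:
    """Parameterisation of a recruitment decision rule.

    Use the :func:`eighty_twenty` / :func:`mean_threshold` constructors
    rather than instantiating directly.
    """

    kind: str  # "eighty_twenty" | "mean_threshold"
    equipoise_point: float = 0.5
    q: float = 0.2
    lo: float = 0.4
    hi: float = 0.7

    def __post_init__(self) -> None:
        if self.kind not in ("eighty_twenty", "mean_threshold"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if not 0.0 < self.q < 0.5:
            raise ValueError("split q must lie in (0, 0.5)")
        if not 0.0 < self.lo < self.hi < 1.0:
            raise ValueError("thresholds must satisfy 0 < lo < hi < 1")
        if not 0.0 < self.equipoise_point < 1.0:
            raise ValueError("equipoise point must lie in (0, 1)")

    def describe(self) -> dict:
        if self.kind == "eighty_twenty":
            return {"rule": "eighty_twenty", "q": self.q,
                    "equipoise_point": self.equipoise_point}
        return {"rule": "mean_threshold", "lo": self.lo, "hi": self.hi}


def eighty_twenty(equipoise_point: float | str = 0.5, q: float = 0.2) -> DecisionRule:
    """The 80:20 rule at a given equipoise point (fraction strings accepted)."""
    return DecisionRule(kind="eighty_twenty",
                        equipoise_point=parse_fraction(equipoise_point), q=q)


def mean_threshold(lo: float = 0.4, hi: float = 0.7) -> DecisionRule:
    """Mean-threshold rule: equipoise while lo <= mu <= hi."""
    return DecisionRule(kind="mean_threshold", lo=lo, hi=hi)


def heel_trial_rule() -> DecisionRule:
    """80:20 rule with the off-centre equipoise point 8/14.

    On a seven-category scale where surgery is an active intervention, the
    equipoise point sits at the division between "no difference" and "a bit
    better" rather than at the centre.
    """
    return eighty_twenty(equipoise_point="8/14")


def classify_80_20(alpha: float, beta: float, rule: DecisionRule) -> Region:
    """Classify Beta shapes under the 80:20 rule via the CDF at equipoise."""
    if rule.kind != "eighty_twenty":
        raise ValueError("rule is not an 80:20 rule")
    if alpha < 1 or beta < 1:
        raise ValueError("shape parameters must be >= 1")
    p_below = float(stats.beta.cdf(rule.equipoise_point, alpha, beta))
    if abs(p_below - rule.q) <= BOUNDARY_TOL or abs(p_below - (1 - rule.q)) <= BOUNDARY_TOL:
        return Region.EQUIPOISE
    if p_below < rule.q:
        return Region.BELIEF
    if p_below > 1.0 - rule.q:
        return Region.DISBELIEF
    return Region.EQUIPOISE


def classify_mean_threshold(alpha: float, beta: float, rule: DecisionRule) -> Region:
    """Classify by pooled mean mu = alpha / (alpha + beta); closed interval is equipoise."""
    if rule.kind != "mean_threshold":
        raise ValueError("rule is not a mean-threshold rule")
    mu = alpha / (alpha + beta)
    if mu > rule.hi + BOUNDARY_TOL:
        return Region.BELIEF
    if mu < rule.lo - BOUNDARY_TOL:
        return Region.DISBELIEF
    return Region.EQUIPOISE


def classify(alpha: float, beta: float, rule: DecisionRule) -> Region:
    """Dispatch to the classifier matching the rule kind."""
    if rule.kind == "eighty_twenty":
        return classify_80_20(alpha, beta, rule)
    return classify_mean_threshold(alpha, beta, rule)


def trace_boundary_80_20(
    rule: DecisionRule,
    side: str,
    n_points: int = 200,
    alpha_max: float = 400.0,
) -> list[Opinion]:
    """Trace one boundary curve of the 80:20 rule in opinion space.

    For a log-spaced grid of alpha >= 1 the beta >= 1 solving
    ``BetaCDF(e; alpha, beta) = q`` (belief side) or ``= 1 - q``
    (disbelief side) is root-found by interval search; each solution maps
    through the opinion equations.  Grid points with no root in
    beta in [1, 1000] are skipped with a warning.  Points are returned in
    order of increasing uncertainty.
    """
    if rule.kind != "eighty_twenty":
        raise ValueError("rule is not an 80:20 rule")
    if side not in ("belief", "disbelief"):
        raise ValueError("side must be 'belief' or 'disbelief'")
    target = rule.q if side == "belief" else 1.0 - rule.q
    e = rule.equipoise_point
    opinions: list[Opinion] = []
    skipped = 0
    for alpha in np.geomspace(1.0, alpha_max, n_points):
        def f(beta: float, a: float = alpha) -> float:
            return float(stats.beta.cdf(e, a, beta)) - target

        lo, hi = 1.0, _BETA_MAX
        if f(lo) * f(hi) > 0:  # CDF is monotone increasing in beta
            skipped += 1
            continue
        beta = optimize.brentq(f, lo, hi, xtol=1e-10)
        opinions.append(opinion_from_beta(float(alpha), float(beta)))
    if skipped:
        warnings.warn(
            f"{skipped} of {n_points} grid points had no boundary solution "
            f"with beta in [1, {_BETA_MAX:g}]",
            UserWarning,
            stacklevel=2,
        )
    opinions.sort(key=lambda o: o.uncertainty)
    return opinions


@dataclass(frozen=True)
class MeanBoundary:
    """Closed-form boundary line of a mean threshold in opinion space.

    For a fixed mean mu0 the constraint mu0 (alpha + beta) = alpha gives
    the line  b = mu0 - (1 - mu0) u,  d = (1 - mu0) - mu0 u,  valid from
    u = 0 up to the first component reaching zero.
    """

    mu: float
    u_max: float
    start: Opinion  # u = 0 endpoint
    end: Opinion  # u = u_max endpoint

    def opinion_at(self, u: float) -> Opinion:
        if not 0.0 <= u <= self.u_max + BOUNDARY_TOL:
            raise ValueError(f"u must lie in [0, {self.u_max}]")
        u = min(u, self.u_max)
        b = self.mu - (1.0 - self.mu) * u
        d = (1.0 - self.mu) - self.mu * u
        return Opinion(max(b, 0.0), max(d, 0.0), u)

    def points(self, n: int = 50) -> list[Opinion]:
        return [self.opinion_at(u) for u in np.linspace(0.0, self.u_max, n)]


def trace_boundary_mean(mu0: float) -> MeanBoundary:
    """Boundary of the mean-threshold rule at mean mu0 in closed form."""
    if not 0.0 < mu0 < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    # b = 0 at u = mu0/(1-mu0); d = 0 at u = (1-mu0)/mu0; the first wins.
    u_max = min(mu0 / (1.0 - mu0), (1.0 - mu0) / mu0)
    b_end = max(mu0 - (1.0 - mu0) * u_max, 0.0)
    d_end = max((1.0 - mu0) - mu0 * u_max, 0.0)
    return MeanBoundary(
        mu=mu0,
        u_max=u_max,
        start=Opinion(mu0, 1.0 - mu0, 0.0),
        end=Opinion(b_end, d_end, u_max),
    )
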