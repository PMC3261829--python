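"""Panel resampling: exact permutation null distribution and eligibility test.

Resampling panels of experts with replacement maps out the full range of
pooled opinions any composition of the observed panel could produce —
including, at the extreme, a panel made of n copies of a single expert.
Because pooling is a symmetric function of its members, with-replacement
panels are *multisets*: a panel of n experts admits C(2n - 1, n) distinct
compositions, small enough to enumerate exhaustively for the panel sizes
encountered in practice (462 compositions at n = 6).  For larger panels a
seeded bootstrap with M draws approximates the same distribution.

The eligibility test takes "this case should not be recruited" as the null
hypothesis: each resampled pooled opinion is classified against the chosen
decision rule, and the p-value is the fraction of compositions falling
outside the equipoise region (belief and disbelief exceedances counted
together).  The case is eligible when that fraction is below the stated
significance level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np

from .beta_model import BetaFit, Opinion, PooledBeta, opinion_from_beta, pool_beta
from .decision_rules import DecisionRule, Region, classify

__all__ = [
    "ResampleResult",
    "enumerate_multisets",
    "n_multisets",
    "resample_opinions",
    "permutation_test",
    "bootstrap_opinion_interval",
]

#: Beyond this panel size exhaustive enumeration is refused
#: (C(2n - 1, n) grows as ~4^n); use the bootstrap instead.
EXHAUSTIVE_LIMIT = 12

#: Panel size above which :func:`permutation_test` defaults to bootstrap.
AUTO_BOOTSTRAP_ABOVE = 8

DEFAULT_BOOTSTRAP_M = 1000


def n_multisets(n: int) -> int:
    """Number of size-n multisets drawn from n experts: C(2n - 1, n)."""
    return comb(2 * n - 1, n)


def enumerate_multisets(n: int):
    """Yield every size-n multiset of expert indices {1..n} exactly once.

    Multisets are emitted as sorted tuples in lexicographic order; ordering
    within a panel is irrelevant because pooling is symmetric.
    """
    if n < 1:
        raise ValueError("panel size must be at least 1")
    if n > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"exhaustive enumeration refused for n = {n} "
            f"({n_multisets(n)} compositions); use the bootstrap instead"
        )
    return itertools.combinations_with_replacement(range(1, n + 1), n)


def resample_opinions(
    fits: list[BetaFit],
    method: str = "exhaustive",
    M: int | None = None,
    seed: int | None = None,
) -> list[tuple[PooledBeta, Opinion]]:
    """Pool every resampled panel composition and map it to an opinion.

    Exhaustive mode enumerates all multisets in canonical (lexicographic)
    order; bootstrap mode draws ``M`` with-replacement panels using the
    given seed.  Each composition's pooled shapes are the means of the
    selected members' (alpha, beta).
    """
    if not fits:
        raise ValueError("need at least one fit")
    n = len(fits)
    alphas = np.array([f.alpha for f in fits])
    betas = np.array([f.beta for f in fits])
    if method == "exhaustive":
        index_sets = [np.array(s) - 1 for s in enumerate_multisets(n)]
    elif method == "bootstrap":
        if M is None or M < 1:
            raise ValueError("bootstrap requires M >= 1")
        if seed is None:
            raise ValueError("bootstrap requires a seed for reproducibility")
        rng = np.random.default_rng(seed)
        index_sets = list(rng.integers(0, n, size=(M, n)))
    else:
        raise ValueError(f"unknown method {method!r}")
    out: list[tuple[PooledBeta, Opinion]] = []
    for idx in index_sets:
        pooled = PooledBeta(
            alpha_bar=float(alphas[idx].mean()),
            beta_bar=float(betas[idx].mean()),
            n_members=n,
        )
        out.append((pooled, opinion_from_beta(pooled.alpha_bar, pooled.beta_bar)))
    return out


@dataclass(frozen=True)
class ResampleResult:
    """Region counts, p-value and eligibility verdict for one case."""

    case_id: str
    rule: DecisionRule
    counts: dict[str, int]
    total: int
    p_value: float
    level: float
    eligible: bool
    method: str
    seed: int | None = None
    pooled: PooledBeta | None = None
    opinion: Opinion | None = None
    resampled: list[tuple[PooledBeta, Opinion]] = field(default=None, repr=False)

    @property
    def p_value_fraction(self) -> str:
        outside = self.counts["belief"] + self.counts["disbelief"]
        return f"{outside}/{self.total}"

    def to_dict(self) -> dict:
        payload = {
            "case_id": self.case_id,
            "rule": self.rule.describe(),
            "counts": dict(self.counts),
            "total": self.total,
            "p_value": self.p_value,
            "p_value_fraction": self.p_value_fraction,
            "eligible": self.eligible,
            "level": self.level,
            "method": self.method,
        }
        if self.method == "bootstrap":
            payload["seed"] = self.seed
        if self.pooled is not None:
            payload["pooled"] = {"alpha_bar": self.pooled.alpha_bar,
                                 "beta_bar": self.pooled.beta_bar}
        if self.opinion is not None:
            payload["opinion"] = self.opinion.to_dict()
        return payload


def permutation_test(
    fits: list[BetaFit],
    rule: DecisionRule,
    level: float = 0.05,
    method: str | None = None,
    M: int = DEFAULT_BOOTSTRAP_M,
    seed: int | None = None,
    case_id: str = "",
    keep_resamples: bool = False,
) -> ResampleResult:
    """Exact (or bootstrap) eligibility test for one case.

    Every resampled pooled opinion is classified by ``rule``; the p-value
    for the null hypothesis "do not recruit" is the exact fraction of
    compositions classified outside equipoise, and the case is eligible
    when p < level.  ``method`` defaults to exhaustive enumeration for
    panels of up to 8 experts and to the bootstrap beyond that.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("significance level must lie in (0, 1)")
    if method is None:
        method = "exhaustive" if len(fits) <= AUTO_BOOTSTRAP_ABOVE else "bootstrap"
    resampled = resample_opinions(fits, method=method, M=M, seed=seed)
    counts = {r.value: 0 for r in Region}
    for pooled, _ in resampled:
        counts[classify(pooled.alpha_bar, pooled.beta_bar, rule).value] += 1
    total = len(resampled)
    outside = counts["belief"] + counts["disbelief"]
    p_value = float(Fraction(outside, total))
    pooled_all = pool_beta(fits)
    return ResampleResult(
        case_id=case_id,
        rule=rule,
        counts=counts,
        total=total,
        p_value=p_value,
        level=level,
        eligible=p_value < level,
        method=method,
        seed=seed if method == "bootstrap" else None,
        pooled=pooled_all,
        opinion=opinion_from_beta(pooled_all.alpha_bar, pooled_all.beta_bar),
        resampled=resampled if keep_resamples else None,
    )


def bootstrap_opinion_interval(
    fits: list[BetaFit],
    level: float = 0.95,
    M: int = DEFAULT_BOOTSTRAP_M,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for each opinion component.

    A descriptive companion to :func:`permutation_test`; the region-count
    test remains the primary inferential tool.
    """
    resampled = resample_opinions(fits, method="bootstrap", M=M, seed=seed)
    comps = np.array([list(op) for _, op in resampled])
    lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    keys = ("b", "d", "u")
    qs = np.quantile(comps, [lo, hi], axis=0)
    return {k: (float(qs[0, i]), float(qs[1, i])) for i, k in enumerate(keys)}
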