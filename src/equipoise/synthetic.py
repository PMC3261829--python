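"""Bundled example panels and synthetic panel generation.

The heel-fracture example panels — four cases assessed by four to six
foot-and-ankle surgeons on the seven-category effectiveness scale — are
bundled verbatim so the full pipeline runs without any external data.

The synthetic generator builds panels with a known ground truth: each
expert's weight vector starts from the exact bin masses of a generating
Beta(alpha, beta) over K equal-width bins on [0, 1], gets perturbed by
Dirichlet noise whose concentration controls inter-expert disagreement,
and is rounded to integer percentages summing to exactly 100
(largest-remainder rounding), mirroring the elicitation instrument.
Because the ground-truth shapes are known, such panels drive
parameter-recovery checks of the fitting and pooling pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assessments import Assessment, AssessmentSet, RatingScale, make_scale

__all__ = ["PanelSpec", "table1_fixtures", "heel_fracture_panels",
           "generate_panel", "degenerate_cases"]

# Heel-fracture example assessments: per case, one weight row per expert
# over (much worse .. much better).  Panels vary in size (6, 5, 4, 5).
_HEEL_FRACTURE_PANELS: dict[str, list[tuple[int, ...]]] = {
    "case1": [
        (5, 5, 10, 20, 30, 20, 10),
        (5, 5, 25, 50, 15, 0, 0),
        (0, 0, 5, 5, 15, 70, 5),
        (0, 0, 15, 59, 25, 1, 0),
        (0, 5, 10, 30, 45, 10, 0),
        (0, 9, 21, 36, 23, 11, 0),
    ],
    "case2": [
        (0, 0, 10, 15, 40, 30, 5),
        (0, 0, 0, 10, 40, 50, 0),
        (0, 2, 4, 12, 32, 48, 2),
        (0, 0, 10, 13, 35, 40, 2),
        (0, 0, 5, 20, 45, 30, 0),
    ],
    "case3": [
        (10, 10, 15, 20, 20, 15, 10),
        (10, 20, 30, 20, 10, 10, 0),
        (5, 10, 10, 15, 30, 20, 10),
        (5, 15, 20, 20, 20, 15, 5),
    ],
    "case4": [
        (20, 60, 15, 5, 0, 0, 0),
        (5, 85, 10, 0, 0, 0, 0),
        (40, 50, 10, 0, 0, 0, 0),
        (10, 80, 5, 5, 0, 0, 0),
        (20, 70, 5, 5, 0, 0, 0),
    ],
}


def heel_fracture_panels(equipoise_point: str | float = "8/14") -> AssessmentSet:
    """The four bundled heel-fracture cases on the seven-category scale.

    The default equipoise point 8/14 reflects surgery being an active
    intervention: equipoise sits between "no difference" and "a bit
    better" rather than at the scale centre.
    """
    scale = make_scale(7, equipoise_point)
    assessments = [
        Assessment(case_id, f"expert{i}", tuple(float(w) for w in row))
        for case_id, rows in _HEEL_FRACTURE_PANELS.items()
        for i, row in enumerate(rows, start=1)
    ]
    return AssessmentSet(scale=scale, assessments=assessments)


#: Alias kept for discoverability alongside the synthetic generators.
table1_fixtures = heel_fracture_panels


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a synthetic expert panel with known generating shapes.

    ``concentration`` scales the Dirichlet noise: expert weight vectors are
    drawn from Dirichlet(concentration * bin_mass), so larger values mean
    tighter agreement with the generating Beta (the noise-free limit as
    concentration -> infinity).
    """

    n_experts: int = 6
    n_categories: int = 7
    true_alpha: float = 5.0
    true_beta: float = 2.0
    concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_alpha < 1 or self.true_beta < 1:
            raise ValueError("generating shapes must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.n_experts < 1 or self.n_categories < 3:
            raise ValueError("need at least 1 expert and 3 categories")


def _largest_remainder_round(proportions: np.ndarray, total: int = 100) -> np.ndarray:
    """Round proportions to integers summing exactly to ``total``."""
    raw = proportions / proportions.sum() * total
    floors = np.floor(raw).astype(int)
    short = total - int(floors.sum())
    # Distribute the remaining units to the largest fractional parts.
    order = np.argsort(-(raw - floors), kind="stable")
    floors[order[:short]] += 1
    return floors


def bin_masses(alpha: float, beta: float, n_categories: int) -> np.ndarray:
    """Probability mass of Beta(alpha, beta) in K equal-width bins on [0, 1]."""
    edges = np.linspace(0.0, 1.0, n_categories + 1)
    cdf = stats.beta.cdf(edges, alpha, beta)
    return np.diff(cdf)


def generate_panel(spec: PanelSpec) -> AssessmentSet:
    """Generate one synthetic case ("synthetic") from a panel recipe.

    Deterministic for a fixed seed.  With infinite concentration every
    expert reports exactly the rounded bin masses of the generating Beta.
    """
    rng = np.random.default_rng(spec.seed)
    masses = bin_masses(spec.true_alpha, spec.true_beta, spec.n_categories)
    scale = make_scale(spec.n_categories)
    assessments = []
    for i in range(1, spec.n_experts + 1):
        if np.isinf(spec.concentration):
            noisy = masses
        else:
            noisy = rng.dirichlet(spec.concentration * np.maximum(masses, 1e-12))
        weights = _largest_remainder_round(noisy)
        assessments.append(
            Assessment("synthetic", f"expert{i}", tuple(float(w) for w in weights))
        )
    return AssessmentSet(scale=scale, assessments=assessments)


def degenerate_cases() -> AssessmentSet:
    """Pathological panels exercising the error paths.

    Case ``single_category``: a point-mass assessment (Beta fitting must
    refuse it); case ``disjoint_support``: two experts with no common
    category (multiplicative pooling is empty); case ``uniform``: an
    expert with equal weight everywhere (fits to the ignorance corner
    alpha = beta = 1).  All are on the seven-category scale.  Constructing
    the set emits the degeneracy warning for the point mass.
    """
    assessments = [
        Assessment("single_category", "point_mass", (0, 0, 0, 100, 0, 0, 0)),
        Assessment("disjoint_support", "low_only", (50, 50, 0, 0, 0, 0, 0)),
        Assessment("disjoint_support", "high_only", (0, 0, 0, 0, 0, 50, 50)),
        Assessment("uniform", "flat", tuple([100.0 / 7.0] * 7)),
    ]
    return AssessmentSet(scale=make_scale(7), assessments=assessments)
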