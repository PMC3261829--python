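"""Expert assessment data model, validation and I/O.

An *assessment* is one expert's elicited probability distribution over an
ordered effectiveness scale, expressed as percentages summing to 100.  The
K ordinal categories are mapped onto the unit interval at the midpoints of
K equal-width bins, ``(2k - 1) / (2K)`` for category ``k = 1..K``, which
preserves the implicit even spacing of the verbal scale and centres it at
1/2.  The *equipoise point* is the location on that transformed scale that
separates "worse" from "better" outcomes; it defaults to 1/2 but may sit
off-centre when one arm is an active intervention (e.g. 8/14 on a
seven-category scale, the division between "no difference" and "a bit
better").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatingScale",
    "Assessment",
    "AssessmentSet",
    "ValidationError",
    "make_scale",
    "validate",
    "load_assessments",
    "save_assessments",
    "parse_fraction",
]

#: Absolute tolerance for the sum-to-100 check.  Inputs are human-entered
#: integer percentages, so strictness catches data-entry errors.
SUM_TOLERANCE = 1e-6

SEVEN_POINT_LABELS = (
    "Much Worse",
    "Significantly Worse",
    "A Bit Worse",
    "No Difference",
    "A Bit Better",
    "Significantly Better",
    "Much Better",
)


class ValidationError(ValueError):
    """Raised when an assessment table violates its invariants."""


def parse_fraction(value: float | int | str) -> float:
    """Parse a number that may be written as a fraction string.

    Rule and scale parameters such as the equipoise point are often stated
    as exact fractions ("8/14"); accepting the string form avoids decimal
    drift in config files.
    """
    if isinstance(value, str):
        return float(Fraction(value))
    return float(value)


@dataclass(frozen=True)
class RatingScale:
    """An ordered K-category effectiveness scale mapped onto (0, 1).

    Parameters
    ----------
    n_categories
        Number of ordinal categories, K >= 3.
    labels
        Category names, lowest to highest effectiveness.
    midpoints
        The transformed location of each category, ``(2k - 1) / (2K)``.
    equipoise_point
        Location in (0, 1) separating "worse" from "better" outcomes.
    """

    n_categories: int
    labels: tuple[str, ...]
    midpoints: tuple[float, ...]
    equipoise_point: float

    def __post_init__(self) -> None:
        if self.n_categories < 3:
            raise ValidationError("a rating scale needs at least 3 categories")
        if len(self.labels) != self.n_categories:
            raise ValidationError("labels must match n_categories")
        if len(self.midpoints) != self.n_categories:
            raise ValidationError("midpoints must match n_categories")
        m = np.asarray(self.midpoints)
        if not (np.all(np.diff(m) > 0) and m[0] > 0 and m[-1] < 1):
            raise ValidationError("midpoints must be strictly increasing inside (0, 1)")
        if not 0 < self.equipoise_point < 1:
            raise ValidationError("equipoise point must lie strictly inside (0, 1)")

    @property
    def midpoint_array(self) -> np.ndarray:
        return np.asarray(self.midpoints, dtype=float)


def make_scale(
    n_categories: int,
    equipoise_point: float | str = "center",
    labels: Sequence[str] | None = None,
) -> RatingScale:
    """Build a K-category scale with midpoints ``(2k - 1) / (2K)``.

    ``equipoise_point`` may be a number, a fraction string such as
    ``"8/14"``, or ``"center"`` (resolves to 1/2).
    """
    if not isinstance(n_categories, (int, np.integer)) or isinstance(n_categories, bool):
        raise ValidationError("n_categories must be an integer")
    if n_categories < 3:
        raise ValidationError("n_categories must be at least 3")
    k = np.arange(1, n_categories + 1)
    midpoints = tuple((2 * k - 1) / (2 * n_categories))
    if equipoise_point == "center":
        e = 0.5
    else:
        e = parse_fraction(equipoise_point)
    if labels is None:
        if n_categories == 7:
            labels = SEVEN_POINT_LABELS
        else:
            labels = tuple(f"category_{i}" for i in k)
    return RatingScale(int(n_categories), tuple(labels), midpoints, e)


@dataclass(frozen=True)
class Assessment:
    """One expert's percentage weights over the K categories for one case."""

    case_id: str
    expert_id: str
    weights: tuple[float, ...]

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    @property
    def probabilities(self) -> np.ndarray:
        """Weights normalised to a probability vector (divide by 100)."""
        return self.weight_array / 100.0

    def is_degenerate(self, scale: RatingScale) -> bool:
        """True when all weight sits in a single category (zero variance)."""
        p = self.probabilities
        mu = float(p @ scale.midpoint_array)
        var = float(p @ (scale.midpoint_array - mu) ** 2)
        return var == 0.0


def validate(assessment: Assessment, scale: RatingScale) -> list[str]:
    """Return the list of invariant violations (empty when valid).

    A degenerate single-category assessment is *valid* but triggers a
    ``UserWarning``; downstream Beta fitting refuses such inputs because a
    point mass has no finite maximum-likelihood shape parameters.
    """
    violations: list[str] = []
    w = assessment.weight_array
    if len(w) != scale.n_categories:
        violations.append(
            f"expected {scale.n_categories} weights, got {len(w)}"
        )
        return violations
    if np.any(w < 0):
        violations.append("weights must be non-negative")
    if abs(w.sum() - 100.0) > SUM_TOLERANCE:
        violations.append(f"weights must sum to 100 (got {w.sum():g})")
    if not violations and assessment.is_degenerate(scale):
        warnings.warn(
            f"degenerate: single category assessment "
            f"({assessment.case_id}/{assessment.expert_id})",
            UserWarning,
            stacklevel=2,
        )
    return violations


@dataclass
class AssessmentSet:
    """A collection of assessments grouped by case, sharing one scale.

    Panels may vary in size between cases; ``n_experts`` is per-case.
    """

    scale: RatingScale
    assessments: list[Assessment] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for a in self.assessments:
            key = (a.case_id, a.expert_id)
            if key in seen:
                raise ValidationError(f"duplicate assessment for {key}")
            seen.add(key)
            problems = validate(a, self.scale)
            if problems:
                raise ValidationError(
                    f"invalid assessment {key}: " + "; ".join(problems)
                )

    @property
    def case_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.assessments:
            if a.case_id not in out:
                out.append(a.case_id)
        return out

    def for_case(self, case_id: str) -> list[Assessment]:
        found = [a for a in self.assessments if a.case_id == case_id]
        if not found:
            raise KeyError(f"no assessments for case {case_id!r}")
        return found

    def n_experts(self, case_id: str) -> int:
        return len(self.for_case(case_id))

    def to_frame(self) -> pd.DataFrame:
        """Wide table: ``case_id, expert_id, c1..cK``."""
        cols = [f"c{i}" for i in range(1, self.scale.n_categories + 1)]
        rows = [
            {"case_id": a.case_id, "expert_id": a.expert_id,
             **dict(zip(cols, a.weights))}
            for a in self.assessments
        ]
        return pd.DataFrame(rows, columns=["case_id", "expert_id", *cols])


def _set_from_rows(
    scale: RatingScale, rows: Iterable[tuple[str, str, Sequence[float]]]
) -> AssessmentSet:
    assessments = [
        Assessment(str(case), str(expert), tuple(float(w) for w in weights))
        for case, expert, weights in rows
    ]
    return AssessmentSet(scale=scale, assessments=assessments)


def load_assessments(
    path: str | Path,
    format: str | None = None,
    scale: RatingScale | None = None,
) -> AssessmentSet:
    """Read an assessment table from CSV or JSON.

    CSV files carry columns ``case_id, expert_id, c1..cK`` (one row per
    expert per case) and need an explicit ``scale`` unless K = 7, in which
    case the seven-point scale with a central equipoise point is assumed.
    JSON files embed the scale:
    ``{"scale": {...}, "cases": [{"case_id", "assessments": [...]}]}``.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path)
        cat_cols = [c for c in df.columns if c not in ("case_id", "expert_id")]
        if scale is None:
            scale = make_scale(len(cat_cols))
        rows = [
            (r["case_id"], r["expert_id"], [r[c] for c in cat_cols])
            for _, r in df.iterrows()
        ]
        return _set_from_rows(scale, rows)
    if fmt == "json":
        payload = json.loads(path.read_text())
        s = payload["scale"]
        scale = make_scale(
            s["n_categories"],
            s.get("equipoise_point", "center"),
            s.get("labels"),
        )
        rows = [
            (case["case_id"], a["expert_id"], a["weights"])
            for case in payload["cases"]
            for a in case["assessments"]
        ]
        return _set_from_rows(scale, rows)
    raise ValidationError(f"unsupported format {fmt!r}")


def save_assessments(aset: AssessmentSet, path: str | Path, format: str | None = None) -> None:
    """Write an assessment table to CSV or JSON (inverse of load)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        aset.to_frame().to_csv(path, index=False)
        return
    if fmt == "json":
        payload = {
            "scale": {
                "n_categories": aset.scale.n_categories,
                "equipoise_point": aset.scale.equipoise_point,
                "labels": list(aset.scale.labels),
            },
            "cases": [
                {
                    "case_id": cid,
                    "assessments": [
                        {"expert_id": a.expert_id, "weights": list(a.weights)}
                        for a in aset.for_case(cid)
                    ],
                }
                for cid in aset.case_ids
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
        return
    raise ValidationError(f"unsupported format {fmt!r}")
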