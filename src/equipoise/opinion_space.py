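"""Ternary opinion space: simplex coordinates and rendering.

A (b, d, u) opinion lives on the 2-simplex and is drawn inside an
equilateral triangle with *disbelief* at the left vertex (0, 0), *belief*
at the right vertex (1, 0) and *uncertainty* at the apex (1/2, sqrt(3)/2).
The mapping

    x = b + u / 2,    y = u * sqrt(3) / 2

is affine and injective, so plot coordinates can be inverted back to the
triplet exactly.  Decision-rule boundaries partition the triangle into
belief / equipoise / disbelief regions; resampled panel opinions are drawn
as a point cloud whose spread shows how much the experts disagree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; figures are written to files
import matplotlib.pyplot as plt
import numpy as np

from .beta_model import Opinion
from .decision_rules import DecisionRule, trace_boundary_80_20, trace_boundary_mean

__all__ = ["TernaryPoint", "ternary_coordinates", "opinion_from_ternary",
           "plot_opinion_space"]

_SQRT3_2 = np.sqrt(3.0) / 2.0

#: Triangle vertices: disbelief, belief, uncertainty.
TRIANGLE = ((0.0, 0.0), (1.0, 0.0), (0.5, _SQRT3_2))


@dataclass(frozen=True)
class TernaryPoint:
    """Cartesian plot coordinates of an opinion inside the triangle."""

    x: float
    y: float


def ternary_coordinates(opinion: Opinion) -> TernaryPoint:
    """Map an opinion to triangle coordinates (disbelief left, belief right)."""
    b, _, u = opinion.as_tuple()
    return TernaryPoint(x=b + u / 2.0, y=u * _SQRT3_2)


def opinion_from_ternary(point: TernaryPoint) -> Opinion:
    """Invert the coordinate mapping back to a (b, d, u) triplet."""
    u = point.y / _SQRT3_2
    b = point.x - u / 2.0
    return Opinion(belief=b, disbelief=1.0 - b - u, uncertainty=u)


def _draw_frame(ax: plt.Axes) -> None:
    xs, ys = zip(*TRIANGLE, TRIANGLE[0])
    ax.plot(xs, ys, color="black", lw=1.0)
    ax.text(-0.02, -0.03, "disbelief", ha="right", va="top")
    ax.text(1.02, -0.03, "belief", ha="left", va="top")
    ax.text(0.5, _SQRT3_2 + 0.03, "uncertainty", ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.axis("off")


def _draw_rule(ax: plt.Axes, rule: DecisionRule) -> None:
    if rule.kind == "eighty_twenty":
        style = {"color": "tab:red", "ls": "--", "lw": 1.2}
        for side in ("belief", "disbelief"):
            with warnings.catch_warnings():
                # grid points beyond the curve's support are routinely skipped
                warnings.simplefilter("ignore", UserWarning)
                curve = trace_boundary_80_20(rule, side)
            pts = [ternary_coordinates(o) for o in curve]
            if pts:
                ax.plot([p.x for p in pts], [p.y for p in pts], **style)
    else:
        style = {"color": "tab:blue", "ls": "-.", "lw": 1.2}
        for mu0 in (rule.lo, rule.hi):
            pts = [ternary_coordinates(o)
                   for o in trace_boundary_mean(mu0).points(50)]
            ax.plot([p.x for p in pts], [p.y for p in pts], **style)


def plot_opinion_space(
    points: Iterable[tuple[Opinion, str]] = (),
    rules: Sequence[DecisionRule] = (),
    out: str | Path | None = None,
    highlight: Opinion | None = None,
    title: str | None = None,
):
    """Render the ternary opinion space with rule boundaries and opinions.

    ``points`` are (opinion, label) pairs drawn as a cloud, with one shared
    legend entry per distinct label; ``highlight`` (typically the pooled
    panel opinion) is drawn as a large marker.  Writes SVG or PNG according
    to the suffix of ``out``; returns the matplotlib figure.
    """
    fig, ax = plt.subplots(figsize=(6, 5.5))
    _draw_frame(ax)
    for rule in rules:
        _draw_rule(ax, rule)
    by_label: dict[str, list[TernaryPoint]] = {}
    for opinion, label in points:
        by_label.setdefault(label, []).append(ternary_coordinates(opinion))
    for label, pts in by_label.items():
        ax.scatter([p.x for p in pts], [p.y for p in pts], s=12, alpha=0.5,
                   label=label or None)
    if highlight is not None:
        p = ternary_coordinates(highlight)
        ax.scatter([p.x], [p.y], s=120, marker="o", facecolor="black",
                   zorder=5, label="pooled opinion")
    if by_label or highlight is not None:
        ax.legend(loc="upper right", frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    if rules:
        meta = "; ".join(str(r.describe()) for r in rules)
        fig.text(0.01, 0.01, meta, fontsize=6, color="grey")
    if out is not None:
        fig.savefig(Path(out), bbox_inches="tight")
        plt.close(fig)
    return fig
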