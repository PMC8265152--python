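"""Gini-coefficient selection of the maximum reported cluster size (MRCS).

Scanning is done once at a fixed maximum scanning window size (MSWS); only the
*reporting* bound is varied afterwards.  Re-scanning at different window sizes
would re-run the hypothesis test and create a multiple-testing problem, whereas
different MRCS values merely re-filter one ranked list of candidates whose
p-values are already fixed.

For a candidate MRCS, the significant non-overlapping clusters (ordered by
significance) define a Lorenz curve: x_k is the cumulative proportion of
non-censored subjects in clusters 1..k, y_k the cumulative proportion of the
observed-time sum.  Short-survival clusters put many events into little total
time, so the curve bows below the 45-degree line; the Gini coefficient — twice
the area between curve and line — measures how sharply the reported set of
clusters separates short survival from the rest.  The MRCS with the largest
Gini coefficient is reported as optimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .scan import ClusterResult, ScanTotals, hierarchical_report

__all__ = [
    "DEFAULT_MRCS_GRID",
    "LorenzPoint",
    "MrcsEvaluation",
    "lorenz_points",
    "gini_coefficient",
    "optimize_mrcs",
]

# Conventional candidate grid of reported-cluster size bounds (fractions of the
# total subject count), the same grid scan software uses for count data.
DEFAULT_MRCS_GRID: tuple[float, ...] = (
    0.03, 0.04, 0.05, 0.06, 0.08, 0.10, 0.12, 0.15,
    0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50,
)


@dataclass(frozen=True)
class LorenzPoint:
    """One Lorenz-curve vertex: cumulative event share x, time share y."""

    x: float
    y: float


@dataclass(frozen=True)
class MrcsEvaluation:
    """One grid value: the clusters it reports, their Lorenz curve and Gini."""

    mrcs: float
    reported: tuple[ClusterResult, ...]
    lorenz: tuple[LorenzPoint, ...]
    gini: float


def lorenz_points(
    reported: Sequence[ClusterResult], totals: ScanTotals
) -> list[LorenzPoint]:
    """Lorenz-curve vertices of a disjoint cluster list ordered by significance.

    Point k has x = (sum of r_in over clusters 1..k) / R and
    y = (sum of t_in over clusters 1..k) / T.
    """
    if totals.R <= 0:
        raise ValueError("need at least one event to build a Lorenz curve")
    seen: set[int] = set()
    points: list[LorenzPoint] = []
    cum_r = 0.0
    cum_t = 0.0
    for cluster in reported:
        members = cluster.zone.member_set()
        if seen & members:
            raise ValueError("overlapping clusters cannot form a Lorenz curve")
        seen |= members
        cum_r += cluster.r_in
        cum_t += cluster.tsum_in
        points.append(LorenzPoint(cum_r / totals.R, cum_t / totals.T))
    return points


def gini_coefficient(points: Sequence[LorenzPoint]) -> float:
    """Twice the signed area between the Lorenz curve and the 45-degree line.

    Computed as sum_{k=1}^{K+1} (y_k * x_{k-1} - y_{k-1} * x_k) over the
    closed polyline (0,0), (x_1,y_1), ..., (x_K,y_K), (1,1).  An empty report
    has no curve and scores 0.
    """
    if not points:
        return 0.0
    xs = [0.0] + [p.x for p in points] + [1.0]
    ys = [0.0] + [p.y for p in points] + [1.0]
    return float(sum(ys[k] * xs[k - 1] - ys[k - 1] * xs[k] for k in range(1, len(xs))))


def optimize_mrcs(
    ranked: Sequence[ClusterResult],
    grid: Sequence[float],
    alpha: float,
    totals: ScanTotals,
    msws: float = 0.5,
) -> tuple[list[MrcsEvaluation], float]:
    """Evaluate every MRCS on the grid and pick the one with the largest Gini.

    ``ranked`` must come from a single scan at the full MSWS, with p-values
    assigned.  Ties in the Gini coefficient go to the smallest grid value (the
    most refined report).  When no cluster is significant at any grid value,
    every Gini is 0 and the largest grid value is returned with its (empty)
    report, so the caller can tell "nothing significant" from a genuine
    selection.
    """
    if not grid:
        raise ValueError("empty MRCS grid")
    if any(not 0 < g <= msws for g in grid):
        raise ValueError("every MRCS grid value must lie in (0, msws]")
    evaluations: list[MrcsEvaluation] = []
    for mrcs in grid:
        reported = hierarchical_report(ranked, mrcs, alpha, totals, msws=msws)
        pts = lorenz_points(reported, totals)
        evaluations.append(
            MrcsEvaluation(mrcs, tuple(reported), tuple(pts), gini_coefficient(pts))
        )
    if all(len(ev.reported) == 0 for ev in evaluations):
        optimal = max(ev.mrcs for ev in evaluations)
        return evaluations, optimal
    best = max(evaluations, key=lambda ev: (ev.gini, -ev.mrcs))
    return evaluations, best.mrcs
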