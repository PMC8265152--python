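"""Shared independent oracles for the test suite.

These re-derive expected results with plain loops and library calls, staying
independent of the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_elliptic_distance(center, p, ratio, angle):
    dx, dy = p[0] - center[0], p[1] - center[1]
    u = math.cos(angle) * dx + math.sin(angle) * dy
    v = -math.sin(angle) * dx + math.cos(angle) * dy
    return math.sqrt((u / ratio) ** 2 + v**2)


def brute_force_zones(coords, counts, msws, ratios, angles_per_ratio):
    """All distance-sorted prefix member sets, deduplicated, by direct loops.

    Returns a set of frozensets (member sets) — order-free, for comparison
    with the production enumerator's output.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    total = int(sum(counts))
    member_sets: set[frozenset[int]] = set()
    for center in range(n):
        for ratio in ratios:
            n_angles = 1 if ratio == 1.0 else angles_per_ratio.get(ratio, 1)
            for a in range(n_angles):
                angle = a * math.pi / n_angles
                dist = [
                    brute_force_elliptic_distance(coords[center], coords[j], ratio, angle)
                    for j in range(n)
                ]
                order = sorted(range(n), key=lambda j: (dist[j], j))
                center_rank = order.index(center)
                cum = 0
                for k, j in enumerate(order):
                    cum += counts[j]
                    if cum > msws * total:
                        break
                    if cum < 1 or k < center_rank:
                        continue
                    member_sets.add(frozenset(order[: k + 1]))
    return member_sets


def greedy_report_oracle(candidates, mrcs, alpha, N):
    """Brute-force greedy selection: walk candidates in the given order,
    keep significant, size-admissible, disjoint ones."""
    chosen = []
    covered = set()
    for cand in candidates:
        members = set(cand.zone.members)
        if cand.zone.subject_count > mrcs * N:
            continue
        if covered & members:
            continue
        if cand.p_value > alpha:
            break
        chosen.append(cand)
        covered |= members
    return chosen


def shoelace_gini(points):
    """Twice the area of the closed polygon (0,0), points..., (1,1) by the
    classic shoelace formula (closing edge back to the origin)."""
    poly = [(0.0, 0.0)] + [(p.x, p.y) for p in points] + [(1.0, 1.0)]
    twice_area = 0.0
    for i in range(len(poly)):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % len(poly)]
        twice_area += x0 * y1 - x1 * y0
    return twice_area
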