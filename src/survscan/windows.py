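"""Candidate scanning-window (zone) enumeration.

Zones are built the way circular/elliptical scan software builds them: for each
region taken as a window center, and for each window shape (axis ratio and
orientation), the remaining regions are sorted by their elliptic distance from
the center and every prefix of that ordering is a candidate zone, up to the
maximum scanning window size (MSWS) expressed as a fraction of the total number
of subjects at risk.  Zones with identical member sets are emitted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "WindowShape",
    "Zone",
    "DEFAULT_ELLIPSE_RATIOS",
    "DEFAULT_ANGLES_PER_RATIO",
    "CIRCULAR_RATIOS",
    "elliptic_distance",
    "elliptic_distances",
    "enumerate_zones",
    "shapes_for_mode",
]

# Ellipse grid used when "elliptical" windows are requested: the conventional
# set of axis ratios with more orientations for more eccentric shapes.  Ratio 1
# (the circle) is orientation-free and is always part of the elliptical set.
DEFAULT_ELLIPSE_RATIOS: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
DEFAULT_ANGLES_PER_RATIO: dict[float, int] = {
    1.0: 1,
    1.5: 4,
    2.0: 6,
    3.0: 9,
    4.0: 12,
    5.0: 15,
}
CIRCULAR_RATIOS: tuple[float, ...] = (1.0,)


@dataclass(frozen=True)
class WindowShape:
    """Shape of a scanning window: major/minor axis ratio and orientation.

    ``ratio`` >= 1, with 1 meaning a circle; ``angle`` is the orientation of
    the major axis in radians, in [0, pi) (an ellipse is symmetric under a
    half-turn).
    """

    ratio: float = 1.0
    angle: float = 0.0

    def __post_init__(self) -> None:
        if not self.ratio >= 1.0:
            raise ValueError("axis ratio must be >= 1")
        if not (0.0 <= self.angle < math.pi):
            raise ValueError("angle must lie in [0, pi)")


@dataclass(frozen=True)
class Zone:
    """A candidate cluster: the regions inside one (center, shape) window.

    ``members`` keeps the order in which regions enter the window (increasing
    elliptic distance from the center).
    """

    members: tuple[int, ...]
    center_region: int
    shape: WindowShape
    subject_count: int

    def member_set(self) -> frozenset[int]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


def elliptic_distance(center: Sequence[float], p: Sequence[float], shape: WindowShape) -> float:
    """Distance of point ``p`` from ``center`` in the metric of an ellipse.

    The displacement is rotated into the ellipse frame (u along the major
    axis, v along the minor) and the major-axis component shrunk by the axis
    ratio: ``sqrt((u/ratio)^2 + v^2)``.  Points at equal elliptic distance lie
    on a common ellipse; ratio 1 recovers the Euclidean distance.
    """
    dx = p[0] - center[0]
    dy = p[1] - center[1]
    c, s = math.cos(shape.angle), math.sin(shape.angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return math.hypot(u / shape.ratio, v)


def elliptic_distances(coords: np.ndarray, center: Sequence[float], shape: WindowShape) -> np.ndarray:
    """Vectorized :func:`elliptic_distance` from one center to many points."""
    d = np.asarray(coords, dtype=float) - np.asarray(center, dtype=float)
    c, s = math.cos(shape.angle), math.sin(shape.angle)
    u = c * d[:, 0] + s * d[:, 1]
    v = -s * d[:, 0] + c * d[:, 1]
    return np.hypot(u / shape.ratio, v)


def shapes_for_mode(mode: str) -> tuple[tuple[float, ...], Mapping[float, int]]:
    """Ratio/angle grid for a window mode: ``circular`` or ``elliptical``."""
    if mode == "circular":
        return CIRCULAR_RATIOS, {1.0: 1}
    if mode == "elliptical":
        return DEFAULT_ELLIPSE_RATIOS, DEFAULT_ANGLES_PER_RATIO
    raise ValueError(f"unknown window mode {mode!r}")


def enumerate_zones(
    area,
    subjects_per_region: Sequence[int],
    msws: float = 0.5,
    shapes: Sequence[float] = CIRCULAR_RATIOS,
    angles_per_shape: Mapping[float, int] | None = None,
) -> list[Zone]:
    """Enumerate all candidate zones up to the maximum scanning window size.

    For every region as center, every axis ratio in ``shapes`` and every
    orientation (``angles_per_shape[ratio]`` angles evenly spaced in [0, pi)),
    regions are sorted by elliptic distance from the center (ties broken by
    region position) and each prefix of the ordering containing the center,
    at least one subject, and at most ``msws`` x (total subjects) is emitted.
    Prefixes with identical member sets are deduplicated, keeping the first
    encountered.

    ``msws`` is a fraction of the total subject count; the bound is inclusive
    (a zone of exactly half the subjects is allowed at the default 0.5).
    """
    if not 0 < msws <= 1:
        raise ValueError("msws must lie in (0, 1]")
    counts = np.asarray(subjects_per_region, dtype=np.int64)
    if counts.shape != (area.n,):
        raise ValueError("subjects_per_region must align with the study area")
    if (counts < 0).any():
        raise ValueError("negative subject count")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no subjects anywhere in the study area")
    max_subjects = msws * total

    if angles_per_shape is None:
        angles_per_shape = {r: DEFAULT_ANGLES_PER_RATIO.get(r, 1) for r in shapes}

    coords = area.coords
    zones: list[Zone] = []
    seen: set[frozenset[int]] = set()

    for center in range(area.n):
        for ratio in shapes:
            n_angles = 1 if ratio == 1.0 else int(angles_per_shape.get(ratio, 1))
            for a in range(n_angles):
                shape = WindowShape(float(ratio), a * math.pi / n_angles)
                dist = elliptic_distances(coords, coords[center], shape)
                order = np.argsort(dist, kind="stable")  # ties -> lower position
                cum = np.cumsum(counts[order])
                center_rank = int(np.nonzero(order == center)[0][0])
                for k in range(area.n):
                    if cum[k] > max_subjects:
                        break
                    if cum[k] < 1 or k < center_rank:
                        continue  # empty window, or window not yet containing its center
                    members = tuple(int(p) for p in order[: k + 1])
                    key = frozenset(members)
                    if key in seen:
                        continue
                    seen.add(key)
                    zones.append(Zone(members, center, shape, int(cum[k])))
    return zones


def zone_region_matrix(zones: Sequence[Zone], n_regions: int) -> np.ndarray:
    """(n_zones, n_regions) 0/1 membership matrix, used to aggregate per-region
    sums into per-zone sums with one matrix product."""
    mat = np.zeros((len(zones), n_regions), dtype=float)
    for i, z in enumerate(zones):
        mat[i, list(z.members)] = 1.0
    return mat
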