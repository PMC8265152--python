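"""Study-area geography: regions, coordinate files, synthetic maps and planted clusters.

A study area is a list of administrative regions (districts), each reduced to a
planar centroid.  Coordinates are plain Cartesian; no map projection is applied,
because the scanning windows only ever compare centroid distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .windows import WindowShape, elliptic_distances

__all__ = [
    "Region",
    "StudyArea",
    "TrueClusterSpec",
    "CoordinateFormatError",
    "load_coordinates",
    "write_coordinates",
    "generate_grid_geography",
    "plant_true_cluster",
]


class CoordinateFormatError(ValueError):
    """Raised when a coordinates file violates the `<id> <x> <y>` contract."""


@dataclass(frozen=True)
class Region:
    """A single district: an opaque id plus a planar centroid."""

    region_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"region {self.region_id!r}: non-finite coordinates")


class StudyArea:
    """The whole study region: an ordered collection of districts.

    Region order is meaningful — positions 0..n-1 index every per-region array
    in the package, and distance ties during window construction are broken by
    position, so the same file always yields the same zones.
    """

    def __init__(self, regions: Iterable[Region]):
        self.regions: list[Region] = list(regions)
        if not self.regions:
            raise ValueError("a StudyArea needs at least one region")
        self.index: dict[str, int] = {}
        for pos, region in enumerate(self.regions):
            if region.region_id in self.index:
                raise ValueError(f"duplicate region id {region.region_id!r}")
            self.index[region.region_id] = pos
        self._coords = np.array([[r.x, r.y] for r in self.regions], dtype=float)

    @property
    def n(self) -> int:
        return len(self.regions)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of centroids, row i = region at position i."""
        return self._coords

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return f"StudyArea(n={self.n})"


@dataclass(frozen=True)
class TrueClusterSpec:
    """A planted ground-truth cluster for simulation studies."""

    member_regions: frozenset[int]
    shape_label: str  # "circular" | "elliptical" | "irregular"

    def __post_init__(self) -> None:
        if not self.member_regions:
            raise ValueError("a true cluster must contain at least one region")


def _parse_row(fields: Sequence[str], lineno: int) -> Region:
    if len(fields) < 3:
        raise CoordinateFormatError(
            f"line {lineno}: expected `<id> <x> <y>`, got {len(fields)} field(s)"
        )
    region_id = fields[0]
    try:
        x, y = float(fields[1]), float(fields[2])
    except ValueError:
        raise CoordinateFormatError(
            f"line {lineno}: non-numeric coordinate for region {region_id!r}"
        ) from None
    return Region(region_id, x, y)


def _split(line: str, dialect: str) -> list[str]:
    if dialect == "csv":
        return [f.strip() for f in line.split(",")]
    return line.split()


def load_coordinates(path, dialect: str = "auto") -> StudyArea:
    """Read a coordinates file: one region per line, ``<id> <x> <y>``.

    ``dialect`` is ``whitespace``, ``csv`` or ``auto`` (comma-split if the line
    contains a comma).  A single header line is tolerated and skipped when its
    second field is non-numeric.
    """
    regions: list[Region] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            use = dialect
            if dialect == "auto":
                use = "csv" if "," in line else "whitespace"
            fields = _split(line, use)
            if not regions and len(fields) >= 2:
                try:
                    float(fields[1])
                except ValueError:
                    continue  # header row
            region = _parse_row(fields, lineno)
            if region.region_id in seen:
                raise CoordinateFormatError(
                    f"line {lineno}: duplicate region id {region.region_id!r}"
                )
            seen.add(region.region_id)
            regions.append(region)
    if not regions:
        raise CoordinateFormatError(f"{path}: no regions found")
    return StudyArea(regions)


def write_coordinates(area: StudyArea, path, dialect: str = "whitespace") -> None:
    """Write a coordinates file readable by :func:`load_coordinates`."""
    sep = "," if dialect == "csv" else " "
    with open(path, "w") as fh:
        for region in area.regions:
            fh.write(f"{region.region_id}{sep}{region.x!r}{sep}{region.y!r}\n")


def generate_grid_geography(n_rows: int, n_cols: int, spacing: float = 1.0) -> StudyArea:
    """Regular lattice of ``n_rows x n_cols`` regions, ids ``r<i>c<j>``, row-major.

    A synthetic stand-in geography for power studies when a real district map
    is unavailable.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    regions = [
        Region(f"r{i}c{j}", j * spacing, i * spacing)
        for i in range(n_rows)
        for j in range(n_cols)
    ]
    return StudyArea(regions)


def plant_true_cluster(
    area: StudyArea,
    kind: str,
    target_fraction: float | None = None,
    seed_region: int | None = None,
    shape: float = 1.0,
    angle: float = 0.0,
    irregular_members: Iterable[int] | None = None,
) -> TrueClusterSpec:
    """Choose a set of regions to act as the ground-truth cluster.

    ``circular`` takes the ``ceil(target_fraction * n)`` regions nearest (in
    Euclidean distance) to the seed region's centroid; ``elliptical`` does the
    same under the elliptic metric at the given axis ``shape`` ratio and
    ``angle``; ``irregular`` uses exactly the supplied member set.  Distance
    ties are broken by region position, so the planted set is deterministic.
    """
    if kind == "irregular":
        if irregular_members is None:
            raise ValueError("irregular clusters require an explicit member set")
        members = frozenset(int(m) for m in irregular_members)
        if not members or not all(0 <= m < area.n for m in members):
            raise ValueError("irregular member set out of range")
        return TrueClusterSpec(members, "irregular")

    if kind not in ("circular", "elliptical"):
        raise ValueError(f"unknown cluster kind {kind!r}")
    if target_fraction is None or not (0 < target_fraction <= 1):
        raise ValueError("target_fraction must be in (0, 1]")
    if seed_region is None or not (0 <= seed_region < area.n):
        raise ValueError("seed_region out of range")

    k = math.ceil(target_fraction * area.n)
    center = area.coords[seed_region]
    if kind == "circular":
        window = WindowShape(1.0, 0.0)
    else:
        window = WindowShape(shape, angle)
    dist = elliptic_distances(area.coords, center, window)
    # stable sort on distance => ties resolved by region position
    order = np.argsort(dist, kind="stable")
    members = frozenset(int(p) for p in order[:k])
    return TrueClusterSpec(members, kind)
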