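"""Exponential-model spatial scan statistic with Monte Carlo inference.

The scan tests, for every candidate zone z, whether mean survival inside z is
shorter than outside.  With exponentially distributed survival times, observed
times t_i = min(T_i, L_i) and censoring indicators delta_i (1 = event
observed), the log likelihood-ratio of a zone is

    llr(z) = r_in * ln(r_in / t_in) + r_out * ln(r_out / t_out) - R * ln(R / T)

whenever the event rate inside exceeds the rate outside
(r_in / t_in > r_out / t_out, i.e. estimated mean survival is shorter inside),
and 0 otherwise; r_* are non-censored counts, t_* observed-time sums, R and T
their study-wide totals, and any term with a zero count contributes 0.  With no
censoring, r_in, r_out and R coincide with the subject counts n_in, n_out
and N, which recovers the no-censoring form of the statistic.

The maximizing zone is the most likely cluster.  Significance comes from Monte
Carlo permutation: (t, delta) pairs are shuffled across subjects (per-region
subject counts held fixed), the scan is re-run, and the maximum llr of each
replicate forms the null distribution.  Every candidate cluster — most likely
and secondary — is ranked against that same null-maximum distribution, so its
p-value reflects whether it would be significant on its own strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .windows import Zone, zone_region_matrix

__all__ = [
    "SubjectRecord",
    "ScanTotals",
    "ZoneStats",
    "ClusterResult",
    "subjects_to_arrays",
    "compute_totals",
    "zone_loglr",
    "scan_all_zones",
    "monte_carlo_null",
    "mc_p_value",
    "assign_p_values",
    "hierarchical_report",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: home region, observed time, and censoring status.

    ``censored`` is True when the event was *not* observed (delta_i = 0); the
    observed time is then the censoring time, not the survival time.
    """

    region: int
    time: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ValueError("observed time must be positive and finite")

    @property
    def delta(self) -> int:
        return 0 if self.censored else 1


@dataclass(frozen=True)
class ScanTotals:
    """Study-wide totals: subjects N, events R, observed-time sum T."""

    N: int
    R: int
    T: float

    def __post_init__(self) -> None:
        if not (0 <= self.R <= self.N):
            raise ValueError("need 0 <= R <= N")
        if not self.T > 0:
            raise ValueError("total observed time must be positive")


@dataclass(frozen=True)
class ZoneStats:
    """Sufficient statistics of one zone: events, time sum, subjects inside."""

    r_in: int
    tsum_in: float
    n_in: int


@dataclass(frozen=True)
class ClusterResult:
    """A scanned zone with its statistic and (once computed) Monte Carlo p."""

    zone: Zone
    log_lr: float
    r_in: int
    n_in: int
    tsum_in: float
    p_value: float | None = None

    @property
    def mean_survival(self) -> float:
        """Estimated mean survival inside the zone, t_in / r_in."""
        return self.tsum_in / self.r_in if self.r_in > 0 else math.nan

    @property
    def regions(self) -> frozenset[int]:
        return self.zone.member_set()


def subjects_to_arrays(subjects: Sequence[SubjectRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unpack subject records into (regions, times, delta) arrays."""
    regions = np.fromiter((s.region for s in subjects), dtype=np.int64, count=len(subjects))
    times = np.fromiter((s.time for s in subjects), dtype=float, count=len(subjects))
    delta = np.fromiter((s.delta for s in subjects), dtype=float, count=len(subjects))
    return regions, times, delta


def compute_totals(subjects: Sequence[SubjectRecord]) -> ScanTotals:
    _, times, delta = subjects_to_arrays(subjects)
    return ScanTotals(N=len(subjects), R=int(delta.sum()), T=float(times.sum()))


def _xlogx_over(r: float, t: float) -> float:
    """r * ln(r/t) with the 0 * ln(0) convention -> 0."""
    if r == 0:
        return 0.0
    return r * math.log(r / t)


def zone_loglr(stats: ZoneStats, totals: ScanTotals) -> float:
    """Log likelihood-ratio of one zone (0 unless survival is shorter inside).

    One-sided: the statistic is positive only when the event rate inside the
    zone exceeds the outside rate, i.e. the estimated mean survival time is
    smaller inside.
    """
    if totals.R == 0:
        raise ValueError("no events anywhere: the statistic is undefined")
    r_in, t_in = stats.r_in, stats.tsum_in
    r_out = totals.R - r_in
    t_out = totals.T - t_in
    if r_in > 0 and t_in <= 0:
        raise ValueError("events inside a zone with zero observed time")
    if r_out > 0 and t_out <= 0:
        raise ValueError("events outside the zone with zero observed time")
    # rate_in > rate_out, compared by cross-multiplication (times are >= 0)
    if r_in * t_out <= r_out * t_in:
        return 0.0
    return (
        _xlogx_over(r_in, t_in)
        + _xlogx_over(r_out, t_out)
        - _xlogx_over(totals.R, totals.T)
    )


def _loglr_vector(r_in: np.ndarray, t_in: np.ndarray, R: float, T: float) -> np.ndarray:
    """Vectorized zone_loglr over aligned per-zone arrays."""
    r_out = R - r_in
    t_out = T - t_in
    with np.errstate(divide="ignore", invalid="ignore"):
        term_in = np.where(r_in > 0, r_in * np.log(np.where(r_in > 0, r_in, 1.0) / t_in), 0.0)
        term_out = np.where(r_out > 0, r_out * np.log(np.where(r_out > 0, r_out, 1.0) / t_out), 0.0)
    base = R * math.log(R / T)
    shorter_inside = r_in * t_out > r_out * t_in
    return np.where(shorter_inside, term_in + term_out - base, 0.0)


def _per_region_sums(
    regions: np.ndarray, times: np.ndarray, delta: np.ndarray, n_regions: int
) -> tuple[np.ndarray, np.ndarray]:
    t_r = np.bincount(regions, weights=times, minlength=n_regions)
    d_r = np.bincount(regions, weights=delta, minlength=n_regions)
    return t_r, d_r


def _zone_stats_arrays(
    zmat: np.ndarray, regions: np.ndarray, times: np.ndarray, delta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    t_r, d_r = _per_region_sums(regions, times, delta, zmat.shape[1])
    return zmat @ d_r, zmat @ t_r


def scan_all_zones(
    zones: Sequence[Zone], subjects: Sequence[SubjectRecord]
) -> list[ClusterResult]:
    """Evaluate the statistic on every zone; return results ranked by log-LR.

    Ties in log-LR are broken toward fewer members, then toward the lower
    center-region position, so the ranking is deterministic.  p-values are not
    set here; see :func:`monte_carlo_null` / :func:`assign_p_values`.
    """
    if not zones:
        raise ValueError("empty zone list")
    regions, times, delta = subjects_to_arrays(subjects)
    totals = ScanTotals(N=len(subjects), R=int(delta.sum()), T=float(times.sum()))
    if totals.R == 0:
        raise ValueError("no events anywhere: the statistic is undefined")
    n_regions = max(int(regions.max()) + 1, max(max(z.members) for z in zones) + 1)
    zmat = zone_region_matrix(zones, n_regions)
    n_r = np.bincount(regions, minlength=n_regions).astype(float)
    r_in, t_in = _zone_stats_arrays(zmat, regions, times, delta)
    n_in = zmat @ n_r
    llr = _loglr_vector(r_in, t_in, totals.R, totals.T)
    results = [
        ClusterResult(
            zone=z,
            log_lr=float(llr[i]),
            r_in=int(round(r_in[i])),
            n_in=int(round(n_in[i])),
            tsum_in=float(t_in[i]),
        )
        for i, z in enumerate(zones)
    ]
    results.sort(key=lambda c: (-c.log_lr, len(c.zone.members), c.zone.center_region))
    return results


def monte_carlo_null(
    zones: Sequence[Zone],
    subjects: Sequence[SubjectRecord],
    B: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Null distribution of the maximum log-LR under (t, delta) permutation.

    Each replicate shuffles the observed (time, censoring) pairs across all
    subjects — region sizes stay fixed — recomputes every zone's statistic and
    keeps the maximum.  Returns the B replicate maxima.
    """
    if B < 1:
        raise ValueError("need at least one replicate")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    regions, times, delta = subjects_to_arrays(subjects)
    R = float(delta.sum())
    T = float(times.sum())
    if R == 0:
        raise ValueError("no events anywhere: the statistic is undefined")
    n_regions = max(int(regions.max()) + 1, max(max(z.members) for z in zones) + 1)
    zmat = zone_region_matrix(zones, n_regions)
    maxima = np.empty(B, dtype=float)
    for b in range(B):
        perm = rng.permutation(len(times))
        r_in, t_in = _zone_stats_arrays(zmat, regions, times[perm], delta[perm])
        llr = _loglr_vector(r_in, t_in, R, T)
        maxima[b] = llr.max(initial=0.0)
    return maxima


def mc_p_value(observed_loglr: float, null_maxima: Sequence[float]) -> float:
    """Monte Carlo p-value: (1 + #{null maxima >= observed}) / (B + 1)."""
    null_maxima = np.asarray(null_maxima, dtype=float)
    B = len(null_maxima)
    if B < 1:
        raise ValueError("need at least one null replicate")
    return float((1 + int((null_maxima >= observed_loglr).sum())) / (B + 1))


def assign_p_values(
    ranked: Iterable[ClusterResult], null_maxima: Sequence[float]
) -> list[ClusterResult]:
    """Attach a p-value to every candidate against the common null maxima."""
    return [replace(c, p_value=mc_p_value(c.log_lr, null_maxima)) for c in ranked]


def hierarchical_report(
    ranked: Sequence[ClusterResult],
    mrcs: float,
    alpha: float,
    totals: ScanTotals,
    msws: float | None = None,
) -> list[ClusterResult]:
    """Greedy non-overlapping cluster report under a maximum reported size.

    Walk the ranking from the top: drop any zone holding more than
    ``mrcs x N`` subjects, drop any zone sharing a region with a cluster
    already reported, and stop at the first non-significant candidate.  The
    result is a pairwise region-disjoint list: the most likely cluster first,
    then secondary clusters.

    ``mrcs`` only filters what is *reported*; it must not exceed the ``msws``
    the zones were scanned at (pass it to enable the check).
    """
    if msws is not None and mrcs > msws:
        raise ValueError("mrcs cannot exceed the scanned msws")
    if not 0 < mrcs <= 1:
        raise ValueError("mrcs must lie in (0, 1]")
    max_subjects = mrcs * totals.N
    reported: list[ClusterResult] = []
    covered: set[int] = set()
    for cand in ranked:
        if cand.p_value is None:
            raise ValueError("p-values must be assigned before reporting")
        if cand.zone.subject_count > max_subjects:
            continue
        if covered & cand.zone.member_set():
            continue
        if cand.p_value > alpha:
            # candidates are ranked by log-LR against one null distribution,
            # so every later p-value is at least as large: stop here
            break
        reported.append(cand)
        covered |= cand.zone.member_set()
    return reported
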