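"""Case-file input, the end-to-end analysis workflow, and report writers.

Case file format: one subject per line, ``<region_id> <time> <censored>``,
whitespace- or comma-separated.  The third column is the *censoring* flag:
``1`` means the subject was censored (the event was not observed, delta_i = 0)
and ``0`` means the event was observed.  Note this is the opposite polarity of
the event indicator delta used internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geography import StudyArea
from .gini import DEFAULT_MRCS_GRID, MrcsEvaluation, optimize_mrcs
from .scan import (
    ClusterResult,
    ScanTotals,
    SubjectRecord,
    assign_p_values,
    compute_totals,
    monte_carlo_null,
    scan_all_zones,
)
from .windows import enumerate_zones, shapes_for_mode

__all__ = [
    "CaseFormatError",
    "read_cases",
    "write_cases",
    "AnalysisResult",
    "analyze",
    "write_cluster_report",
    "write_gini_table",
    "write_scenario_summary",
]


class CaseFormatError(ValueError):
    """Raised when a case file violates the `<region_id> <time> <censored>` contract."""


def read_cases(path, area: StudyArea, dialect: str = "auto") -> list[SubjectRecord]:
    """Read subject records, mapping region ids to positions in ``area``."""
    subjects: list[SubjectRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            use = dialect
            if dialect == "auto":
                use = "csv" if "," in line else "whitespace"
            fields = [f.strip() for f in line.split(",")] if use == "csv" else line.split()
            if len(fields) < 3:
                raise CaseFormatError(
                    f"line {lineno}: expected `<region_id> <time> <censored>`"
                )
            if not subjects:
                try:
                    float(fields[1])
                except ValueError:
                    continue  # header row
            region_id, time_s, cens_s = fields[0], fields[1], fields[2]
            if region_id not in area.index:
                raise CaseFormatError(
                    f"line {lineno}: unknown region id {region_id!r}"
                )
            try:
                time = float(time_s)
                cens = int(cens_s)
            except ValueError:
                raise CaseFormatError(f"line {lineno}: malformed record") from None
            if cens not in (0, 1):
                raise CaseFormatError(f"line {lineno}: censored flag must be 0 or 1")
            subjects.append(SubjectRecord(area.index[region_id], time, bool(cens)))
    if not subjects:
        raise CaseFormatError(f"{path}: no subjects found")
    return subjects


def write_cases(subjects: Sequence[SubjectRecord], area: StudyArea, path) -> None:
    """Write a case file readable by :func:`read_cases`."""
    with open(path, "w") as fh:
        for s in subjects:
            fh.write(f"{area.regions[s.region].region_id} {s.time!r} {1 if s.censored else 0}\n")


@dataclass
class AnalysisResult:
    """Everything one scan produces: the ranked candidates with p-values, the
    Monte Carlo null maxima, the per-MRCS evaluations and the optimal MRCS."""

    area: StudyArea
    totals: ScanTotals
    ranked: list[ClusterResult]
    null_maxima: np.ndarray
    evaluations: list[MrcsEvaluation]
    optimal_mrcs: float
    default_mrcs: float = 0.5

    def report(self, mrcs: float) -> tuple[ClusterResult, ...]:
        for ev in self.evaluations:
            if ev.mrcs == mrcs:
                return ev.reported
        raise KeyError(f"MRCS {mrcs} was not evaluated")


def analyze(
    area: StudyArea,
    subjects: Sequence[SubjectRecord],
    msws: float = 0.5,
    mrcs_grid: Sequence[float] = DEFAULT_MRCS_GRID,
    window_mode: str = "circular",
    alpha: float = 0.05,
    B: int = 999,
    seed: int | None = None,
) -> AnalysisResult:
    """One full analysis: enumerate zones at the MSWS, scan, Monte Carlo
    p-values (computed once), then the Gini grid search over the MRCS."""
    shapes, angles = shapes_for_mode(window_mode)
    counts = np.bincount([s.region for s in subjects], minlength=area.n)
    zones = enumerate_zones(area, counts, msws, shapes, angles)
    ranked = scan_all_zones(zones, subjects)
    nulls = monte_carlo_null(zones, subjects, B, np.random.default_rng(seed))
    ranked = assign_p_values(ranked, nulls)
    totals = compute_totals(subjects)
    grid = list(mrcs_grid)
    if 0.5 <= msws and 0.5 not in grid:
        grid.append(0.5)
    evaluations, optimal = optimize_mrcs(ranked, grid, alpha, totals, msws)
    return AnalysisResult(area, totals, ranked, nulls, evaluations, optimal)


# ---------------------------------------------------------------------------
# report writers


def _cluster_rows(
    reported: Sequence[ClusterResult], area: StudyArea
) -> list[dict]:
    rows = []
    for rank, c in enumerate(reported, start=1):
        rows.append(
            {
                "cluster": rank,
                "districts": ",".join(area.regions[m].region_id for m in c.zone.members),
                "n_districts": len(c.zone.members),
                "log_lr": round(c.log_lr, 6),
                "p_value": round(c.p_value, 6) if c.p_value is not None else None,
                "mean_survival": round(c.mean_survival, 6),
                "observations": c.n_in,
                "non_censored": c.r_in,
            }
        )
    return rows


def write_cluster_report(
    reported: Sequence[ClusterResult], area: StudyArea, path_stem
) -> None:
    """Write ``<stem>.tsv`` and ``<stem>.json`` cluster tables (one row per
    reported cluster: districts, log-LR, p, mean survival, counts)."""
    rows = _cluster_rows(reported, area)
    stem = Path(path_stem)
    cols = [
        "cluster", "districts", "n_districts", "log_lr",
        "p_value", "mean_survival", "observations", "non_censored",
    ]
    with open(stem.with_suffix(".tsv"), "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(rows, fh, indent=2)
        fh.write("\n")


def write_gini_table(result: AnalysisResult, path_stem) -> None:
    """Write the per-MRCS table: grid value, reported cluster count, Gini,
    and a flag on the optimum."""
    stem = Path(path_stem)
    rows = [
        {
            "mrcs": ev.mrcs,
            "n_clusters": len(ev.reported),
            "gini": round(ev.gini, 6),
            "optimal": ev.mrcs == result.optimal_mrcs,
        }
        for ev in result.evaluations
    ]
    with open(stem.with_suffix(".tsv"), "w") as fh:
        fh.write("mrcs\tn_clusters\tgini\toptimal\n")
        for row in rows:
            fh.write(
                f"{row['mrcs']}\t{row['n_clusters']}\t{row['gini']}\t"
                f"{'*' if row['optimal'] else ''}\n"
            )
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(rows, fh, indent=2)
        fh.write("\n")


def _fmt(value: float) -> str:
    return "-" if value != value else f"{value:.3f}"  # NaN-safe


def write_scenario_summary(result, path_stem) -> None:
    """Write scenario aggregates as a grid-shaped TSV plus JSON.

    Columns are the MRCS grid values plus a Default and an Overall column;
    rows are selection Frequency and the conditional Sensitivity / PPV.
    Accuracy cells condition on the dataset being rejected (at least one
    significant reported cluster); frequencies sum to the number of rejected
    datasets at the Gini-selected MRCS.
    """
    stem = Path(path_stem)
    grid = sorted(result.per_mrcs)
    header = (
        ["row"]
        + [f"{m:g}" for m in grid]
        + [f"default({result.default_mrcs:g})", "overall"]
    )
    freq_row = ["Frequency"] + [
        str(result.gini.frequency.get(m, 0)) for m in grid
    ] + [str(result.default.S), str(result.gini.S)]
    sens_row = ["Sensitivity"] + [
        _fmt(result.per_mrcs[m].sensitivity) for m in grid
    ] + [_fmt(result.default.sensitivity), _fmt(result.gini.sensitivity)]
    ppv_row = ["PPV"] + [
        _fmt(result.per_mrcs[m].ppv) for m in grid
    ] + [_fmt(result.default.ppv), _fmt(result.gini.ppv)]
    with open(stem.with_suffix(".tsv"), "w") as fh:
        fh.write("# accuracy cells condition on per-dataset rejection\n")
        for row in (header, freq_row, sens_row, ppv_row):
            fh.write("\t".join(row) + "\n")
    payload = {
        "n_replicates": result.n_replicates,
        "default_mrcs": result.default_mrcs,
        "gini": {
            "S": result.gini.S,
            "sensitivity": _nan_none(result.gini.sensitivity),
            "ppv": _nan_none(result.gini.ppv),
            "frequency": {f"{m:g}": result.gini.frequency.get(m, 0) for m in grid},
        },
        "default": {
            "S": result.default.S,
            "sensitivity": _nan_none(result.default.sensitivity),
            "ppv": _nan_none(result.default.ppv),
        },
        "per_mrcs": {
            f"{m:g}": {
                "S": result.per_mrcs[m].S,
                "sensitivity": _nan_none(result.per_mrcs[m].sensitivity),
                "ppv": _nan_none(result.per_mrcs[m].ppv),
            }
            for m in grid
        },
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _nan_none(value: float):
    return None if value != value else value
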