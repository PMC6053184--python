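"""Annual statistics, establishment metrics and persistence boundaries.

Headline quantities are measured on active individuals (asexual + sexual)
per class: time-weighted annual means and maxima, per-year class
proportions of the total community, establishment against a detection
threshold, the first year a class exceeds half the community, and the
largest whole-year reduction of the F1 growth rate that still preserves F1
establishment (found by bisection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .model_core import N_CLASSES, YEAR_LENGTH, HybridClass
from .scenarios import R_PARENTAL_HIGH, ScenarioSpec, percent_reduction
from .simulate import SolverSettings, Trajectory, integrate

__all__ = [
    "SummaryReport",
    "DETECTION_THRESHOLD",
    "annual_statistics",
    "establishment_metrics",
    "EstablishmentMetrics",
    "final_decade_proportions",
    "persistence_boundary",
    "bisect_boundary",
    "write_summary",
    "load_summary",
]

DETECTION_THRESHOLD = 0.01  # individuals per litre; continuous densities never hit 0
SCHEMA_VERSION = 1


@dataclass
class SummaryReport:
    """Per-year per-class statistics of a trajectory.

    ``table`` has one row per (year, class): time-weighted annual mean and
    maximum of active density A+S, and the class proportion of the total
    community (ratio of annual means, so proportions sum to one whenever
    the community is non-empty).  Years are numbered from 1.
    """

    table: pd.DataFrame
    scenario_id: str = ""
    report_start_year: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_years(self) -> int:
        return int(self.table["year"].max())

    def class_series(self, j: HybridClass | int, column: str) -> pd.Series:
        j = HybridClass(j)
        sub = self.table[self.table["class_index"] == int(j)]
        return sub.set_index("year")[column]


def annual_statistics(trajectory: Trajectory) -> SummaryReport:
    """Aggregate a trajectory into per-year per-class statistics.

    Year ``y`` (1-based) covers samples with t in [365*(y-1), 365*y); means
    are time-weighted (trapezoidal).  The proportion of class j in year y
    is its annual-mean active density divided by the total annual-mean
    active density.
    """
    t = trajectory.times
    if len(t) < 2 or t[-1] - t[0] < YEAR_LENGTH:
        raise ValueError("trajectory must span at least one full year")
    active = trajectory.active  # (n, 6)
    n_years = int(np.floor((t[-1] + 0.5) / YEAR_LENGTH))

    rows = []
    for y in range(1, n_years + 1):
        lo, hi = (y - 1) * YEAR_LENGTH, y * YEAR_LENGTH
        mask = (t >= lo) & (t <= hi)
        tt = t[mask]
        aa = active[mask]
        span = tt[-1] - tt[0]
        if span <= 0:
            raise ValueError(f"no samples in year {y}")
        means = np.trapezoid(aa, tt, axis=0) / span
        maxima = aa.max(axis=0)
        total = means.sum()
        props = means / total if total > 0 else np.zeros(N_CLASSES)
        for c in HybridClass:
            i = c.array_index
            rows.append(
                {
                    "year": y,
                    "class_index": int(c),
                    "class_role": c.name.lower(),
                    "mean_active": means[i],
                    "max_active": maxima[i],
                    "proportion": props[i],
                }
            )
    return SummaryReport(
        table=pd.DataFrame(rows),
        scenario_id=trajectory.spec.id,
        report_start_year=trajectory.spec.report_start_year,
    )


@dataclass
class EstablishmentMetrics:
    """Establishment summary for one class.

    ``established``: per-year flags (annual mean active density >= the
    detection threshold).  ``onset_year``: first established year (None if
    never).  ``persistence_years``: length of the first consecutive run of
    established years.  ``dominance_year``: first year the class holds more
    than half the community.  Years are counted from ``start_year`` + 1
    (e.g. from the introduction of the second species).
    """

    established: pd.Series
    onset_year: int | None
    persistence_years: int
    dominance_year: int | None


def establishment_metrics(
    report: SummaryReport,
    j: HybridClass | int = HybridClass.F1_HYBRID,
    delta_detect: float = DETECTION_THRESHOLD,
    start_year: int | None = None,
) -> EstablishmentMetrics:
    """Establishment flags, onset, persistence run and dominance onset for class j.

    ``start_year`` restricts the analysis to years after it (defaults to
    the report's own reporting offset, i.e. post-introduction years for the
    invasion scenario); returned year numbers are relative to that origin.
    """
    if delta_detect <= 0:
        raise ValueError("delta_detect must be positive")
    start = report.report_start_year if start_year is None else start_year
    mean = report.class_series(j, "mean_active")
    prop = report.class_series(j, "proportion")
    mean = mean[mean.index > start]
    prop = prop[prop.index > start]
    established = mean >= delta_detect
    established.index = established.index - start

    onset = int(established.idxmax()) if established.any() else None
    persistence = 0
    if onset is not None:
        run = established.loc[onset:]
        # length of the first consecutive True run
        for flag in run:
            if not flag:
                break
            persistence += 1
    dom = prop[prop > 0.5]
    dominance_year = int(dom.index.min()) - start if len(dom) else None
    return EstablishmentMetrics(
        established=established,
        onset_year=onset,
        persistence_years=persistence,
        dominance_year=dominance_year,
    )


def final_decade_proportions(report: SummaryReport, n_years: int = 10) -> np.ndarray:
    """Mean per-class proportion over the final ``n_years`` simulation years."""
    last = report.n_years
    sub = report.table[report.table["year"] > last - n_years]
    return (
        sub.groupby("class_index")["proportion"].mean().reindex(range(1, 7)).to_numpy()
    )


def bisect_boundary(
    predicate: Callable[[float], bool],
    lo: float,
    hi: float,
    tol: float = 1e-4,
) -> float:
    """Bisect for the smallest x in [lo, hi] where ``predicate`` holds.

    Requires predicate(hi) true and predicate(lo) false (monotone
    transition); raises otherwise, reporting both endpoint evaluations.
    """
    p_lo, p_hi = predicate(lo), predicate(hi)
    if p_lo == p_hi:
        raise ValueError(
            f"predicate is {p_lo} at both endpoints ({lo}, {hi}); "
            "no boundary bracketed"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def persistence_boundary(
    scenario_builder: Callable[[float], ScenarioSpec],
    r3_low: float,
    r3_high: float = R_PARENTAL_HIGH,
    delta_detect: float = DETECTION_THRESHOLD,
    bisection_tol: float = 1e-4,
    settings: SolverSettings | None = None,
) -> float:
    """Largest percent reduction of r3 (vs 0.35) preserving F1 establishment.

    ``scenario_builder`` maps an F1 growth rate r3 to a ScenarioSpec; the
    predicate is "F1-hybrids established (annual-mean active density >=
    delta_detect) in the final simulation year".  Bisects r3 between
    ``r3_low`` and ``r3_high`` and returns 100*(0.35 - r3*)/0.35 at the
    boundary.
    """

    def established_at(r3: float) -> bool:
        report = annual_statistics(integrate(scenario_builder(r3), settings))
        final_year_mean = report.class_series(HybridClass.F1_HYBRID, "mean_active").iloc[-1]
        return bool(final_year_mean >= delta_detect)

    r3_star = bisect_boundary(established_at, r3_low, r3_high, tol=bisection_tol)
    return percent_reduction(r3_star)


def write_summary(report: SummaryReport, path) -> tuple[Path, Path]:
    """Write a JSON summary and the per-year CSV table.

    ``path`` is the JSON destination; the CSV lands next to it with suffix
    ``.csv``.  The pair round-trips through :func:`load_summary`.
    """
    if report.table.empty:
        raise ValueError("cannot write an empty report")
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    report.table.to_csv(csv_path, index=False, float_format="%.12g")
    payload = {
        "schema_version": SCHEMA_VERSION,
        "scenario": report.scenario_id,
        "report_start_year": report.report_start_year,
        "n_years": report.n_years,
        "final_decade_proportions": final_decade_proportions(report).tolist(),
        "table_csv": csv_path.name,
        "metadata": report.metadata,
    }
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    except OSError as err:
        raise OSError(f"failed writing summary to {path}: {err}") from err
    return path, csv_path


def load_summary(path) -> SummaryReport:
    """Reload a summary written by :func:`write_summary`."""
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    table = pd.read_csv(path.parent / payload["table_csv"])
    return SummaryReport(
        table=table,
        scenario_id=payload["scenario"],
        report_start_year=payload["report_start_year"],
        metadata=payload.get("metadata", {}),
    )
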