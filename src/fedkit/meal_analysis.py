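"""Inter-pellet-interval statistics and meal segmentation.

Mice eat in discrete bouts: the distribution of intervals between
consecutive pellet removals is strongly bimodal, with a large peak below
one minute (within-meal eating) and a long tail of between-meal gaps.
Following that distribution, pellets removed within 60 s of each other are
chained into the same meal, and a cluster must reach a minimum size
(default 5 pellets, i.e. 0.1 g of 20 mg pellets) to count as a meal.
Sub-threshold clusters are kept and reported as *stray* pellets so that
"% of pellets within meals" has a well-defined denominator.

The gap comparison is inclusive (a gap of exactly ``max_gap`` joins the
meal), and chaining is single-linkage: a meal may span far more than
``max_gap`` end-to-end as long as every consecutive gap is short.  A
meal's circadian phase is the phase of its first pellet; meals spanning a
light transition are not split.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .event_log import LightCycle, SessionLog

__all__ = [
    "MealParams",
    "Meal",
    "inter_pellet_intervals",
    "ipi_histogram",
    "segment_meals",
    "meal_summary",
    "meals_to_frame",
]


@dataclass(frozen=True)
class MealParams:
    max_gap: float = 60.0  # s, inclusive chaining threshold
    min_pellets: int = 5
    pellet_mass_mg: float = 20.0

    def __post_init__(self):
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")
        if self.min_pellets < 1:
            raise ValueError("min_pellets must be >= 1")
        if self.pellet_mass_mg <= 0:
            raise ValueError("pellet_mass_mg must be positive")


@dataclass(frozen=True)
class Meal:
    start: datetime
    end: datetime
    pellet_times: tuple[datetime, ...]
    phase: Optional[str] = None  # "dark" | "light", phase of the first pellet

    @property
    def n_pellets(self) -> int:
        return len(self.pellet_times)


def inter_pellet_intervals(log: SessionLog) -> list[float]:
    """Seconds between consecutive pellet events (length = max(n - 1, 0))."""
    times = log.pellet_times
    return [
        (b - a).total_seconds() for a, b in zip(times[:-1], times[1:])
    ]


def ipi_histogram(
    log_or_intervals: SessionLog | Sequence[float],
    light: Optional[LightCycle] = None,
    *,
    n_bins: int = 25,
    span: tuple[float, float] = (1.0, 36000.0),
) -> pd.DataFrame:
    """Histogram of inter-pellet intervals over logarithmically spaced bins.

    Default 25 bins spanning 1 s to 10 h.  Given a :class:`SessionLog` and
    a light cycle, intervals are split by the phase of their *leading*
    pellet into ``dark``/``light`` columns; otherwise a single ``all``
    column is returned.  Bin counts sum to the interval count (intervals
    outside the span are clipped into the edge bins so nothing is lost).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = span
    if lo <= 0 or hi <= lo:
        raise ValueError("span must satisfy 0 < lo < hi")
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)

    if isinstance(log_or_intervals, SessionLog):
        log = log_or_intervals
        times = log.pellet_times
        intervals = np.array(
            [(b - a).total_seconds() for a, b in zip(times[:-1], times[1:])]
        )
        cycle = light or log.light_cycle
        phases = np.array(
            ["light" if cycle.is_light(t) else "dark" for t in times[:-1]]
        )
        columns = {}
        for phase in ("dark", "light"):
            vals = intervals[phases == phase] if len(intervals) else intervals
            columns[phase] = _bin_clipped(vals, edges)
    else:
        intervals = np.asarray(list(log_or_intervals), dtype=float)
        if np.any(intervals < 0):
            raise ValueError("intervals must be non-negative")
        columns = {"all": _bin_clipped(intervals, edges)}

    out = pd.DataFrame(columns)
    out.insert(0, "bin_left", edges[:-1])
    out.insert(1, "bin_right", edges[1:])
    return out


def _bin_clipped(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    if len(values) == 0:
        return np.zeros(len(edges) - 1, dtype=int)
    clipped = np.clip(values, edges[0], np.nextafter(edges[-1], 0))
    counts, _ = np.histogram(clipped, bins=edges)
    return counts


def _clusters(
    pellet_times: Sequence[datetime], params: MealParams
) -> list[list[datetime]]:
    times = list(pellet_times)
    for a, b in zip(times[:-1], times[1:]):
        if b < a:
            raise ValueError("pellet_times must be non-decreasing")
    clusters: list[list[datetime]] = []
    for t in times:
        if clusters and (t - clusters[-1][-1]).total_seconds() <= params.max_gap:
            clusters[-1].append(t)
        else:
            clusters.append([t])
    return clusters


def segment_meals(
    pellet_times: Sequence[datetime],
    params: MealParams = MealParams(),
    light: Optional[LightCycle] = None,
) -> tuple[list[Meal], int]:
    """Chain pellets into meals; returns (meals, stray pellet count).

    Consecutive gaps <= ``max_gap`` extend the running cluster; a larger
    gap starts a new one.  Clusters of at least ``min_pellets`` become
    meals; the rest are counted as strays.  Meal pellets plus strays
    always equal the number of input pellets.
    """
    clusters = _clusters(pellet_times, params)
    meals: list[Meal] = []
    strays = 0
    for cluster in clusters:
        if len(cluster) >= params.min_pellets:
            phase = None
            if light is not None:
                phase = "light" if light.is_light(cluster[0]) else "dark"
            meals.append(
                Meal(
                    start=cluster[0],
                    end=cluster[-1],
                    pellet_times=tuple(cluster),
                    phase=phase,
                )
            )
        else:
            strays += len(cluster)
    return meals, strays


def meal_summary(
    log: SessionLog,
    params: MealParams = MealParams(),
    light: Optional[LightCycle] = None,
    *,
    days: Optional[float] = None,
) -> pd.DataFrame:
    """Per-phase meal microstructure table.

    One row per phase (``dark``, ``light``) with columns ``meals_per_day``,
    ``pellets_per_meal`` (mean) and ``pct_pellets_in_meals``
    (100 x meal pellets / all pellets of that phase; NaN when the phase has
    no pellets).  ``days`` defaults to the log's recording span; a
    zero-duration log is an error because per-day rates are undefined.
    """
    cycle = light or log.light_cycle
    if days is None:
        days = log.duration_days()
    if days <= 0:
        raise ValueError("log spans zero time; per-day rates are undefined")
    # Every pellet inherits the phase of its cluster's first pellet, so a
    # meal straddling the light transition is not split and the in-meal
    # percentage stays within [0, 100].
    clusters = _clusters(log.pellet_times, params)
    rows = []
    for phase in ("dark", "light"):
        phase_clusters = [
            c
            for c in clusters
            if ("light" if cycle.is_light(c[0]) else "dark") == phase
        ]
        phase_meals = [c for c in phase_clusters if len(c) >= params.min_pellets]
        phase_pellets = [t for c in phase_clusters for t in c]
        in_meals = sum(len(c) for c in phase_meals)
        rows.append(
            {
                "phase": phase,
                "n_meals": len(phase_meals),
                "meals_per_day": len(phase_meals) / days,
                "pellets_per_meal": (
                    in_meals / len(phase_meals) if phase_meals else float("nan")
                ),
                "pct_pellets_in_meals": (
                    100.0 * in_meals / len(phase_pellets)
                    if phase_pellets
                    else float("nan")
                ),
                "n_pellets": len(phase_pellets),
            }
        )
    return pd.DataFrame(rows).set_index("phase")


def meals_to_frame(meals: Sequence[Meal]) -> pd.DataFrame:
    """Meal list as a tidy DataFrame (start, end, n_pellets, phase)."""
    return pd.DataFrame(
        {
            "start": [m.start for m in meals],
            "end": [m.end for m in meals],
            "n_pellets": [m.n_pellets for m in meals],
            "phase": [m.phase for m in meals],
        }
    )
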