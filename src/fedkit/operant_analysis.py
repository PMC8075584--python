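"""Operant performance metrics.

Poke counts and efficiency, retrieval-time learning curves, cumulative
records, pokes-per-pellet, progressive-ratio breakpoints, and the
dispensed-mass accounting check (pellet count x pellet mass), computed
from event logs alone.

Binned metrics default to 4-h bins anchored at the recording start, the
granularity at which overnight learning curves are usually displayed;
``bin_width_s`` is configurable throughout.  Efficiency denominators
include non-operant pokes by default (matching "% of total pokes");
``include_nonoperant=False`` restricts to operant pokes.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .event_log import Event, SessionLog
from .task_simulator import TaskSpec

__all__ = [
    "poke_counts",
    "poke_efficiency",
    "retrieval_time_stats",
    "cumulative_records",
    "pokes_per_pellet",
    "breakpoint",
    "replay_ratio_bouts",
    "dispensed_mass",
]

DEFAULT_BIN_S = 4 * 3600.0


def _time_bins(log: SessionLog, bin_width_s: float) -> list[tuple[datetime, datetime]]:
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be > 0")
    start, end = log.span()
    bins = []
    t = start
    while t < end:
        hi = t + timedelta(seconds=bin_width_s)
        bins.append((t, min(hi, end)))
        t = hi
    return bins


def _pokes(log: SessionLog, include_nonoperant: bool) -> list[Event]:
    return [
        e
        for e in log.events
        if e.is_poke and (include_nonoperant or e.operant)
    ]


def poke_counts(
    log: SessionLog, include_nonoperant: bool = True
) -> tuple[int, int]:
    """(active, inactive) poke totals."""
    pokes = _pokes(log, include_nonoperant)
    active = sum(1 for e in pokes if e.is_active_poke)
    return active, len(pokes) - active


def poke_efficiency(
    log: SessionLog,
    *,
    bin_width_s: Optional[float] = None,
    include_nonoperant: bool = True,
):
    """Percent of pokes on the active port, overall or per time bin.

    Returns a float for the whole session (``bin_width_s=None``), else a
    DataFrame with one row per bin.  Windows without pokes report NaN, not
    zero.
    """
    if bin_width_s is None:
        active, inactive = poke_counts(log, include_nonoperant)
        total = active + inactive
        return 100.0 * active / total if total else float("nan")
    pokes = _pokes(log, include_nonoperant)
    rows = []
    for lo, hi in _time_bins(log, bin_width_s):
        in_bin = [e for e in pokes if lo <= e.timestamp < hi]
        active = sum(1 for e in in_bin if e.is_active_poke)
        total = len(in_bin)
        rows.append(
            {
                "bin_start": lo,
                "efficiency_pct": 100.0 * active / total if total else float("nan"),
                "n_pokes": total,
            }
        )
    return pd.DataFrame(rows)


def retrieval_time_stats(
    log: SessionLog, *, bin_width_s: float = DEFAULT_BIN_S
) -> pd.DataFrame:
    """Mean and median retrieval time (s) of pellet events per time bin."""
    pellets = [e for e in log.events if e.event_kind == "Pellet"]
    rows = []
    for lo, hi in _time_bins(log, bin_width_s):
        rts = [e.retrieval_time for e in pellets if lo <= e.timestamp < hi]
        rows.append(
            {
                "bin_start": lo,
                "mean_s": float(np.mean(rts)) if rts else float("nan"),
                "median_s": float(np.median(rts)) if rts else float("nan"),
                "n_pellets": len(rts),
            }
        )
    return pd.DataFrame(rows)


def cumulative_records(log: SessionLog) -> pd.DataFrame:
    """Step functions of cumulative active/inactive pokes and pellets.

    One row per event with the totals *after* that event; terminal values
    equal :func:`poke_counts` and the pellet total.
    """
    active = inactive = pellets = 0
    rows = []
    for e in log.events:
        if e.event_kind == "Pellet":
            pellets += 1
        elif e.is_active_poke:
            active += 1
        else:
            inactive += 1
        rows.append(
            {
                "timestamp": e.timestamp,
                "active": active,
                "inactive": inactive,
                "pellets": pellets,
            }
        )
    return pd.DataFrame(rows, columns=["timestamp", "active", "inactive", "pellets"])


def pokes_per_pellet(
    log: SessionLog,
    *,
    bin_width_s: Optional[float] = None,
    include_nonoperant: bool = True,
):
    """Pokes per earned pellet, overall or per time bin (NaN when 0 pellets)."""
    if bin_width_s is None:
        active, inactive = poke_counts(log, include_nonoperant)
        n = log.n_pellets
        return (active + inactive) / n if n else float("nan")
    pokes = _pokes(log, include_nonoperant)
    pellets = [e for e in log.events if e.event_kind == "Pellet"]
    rows = []
    for lo, hi in _time_bins(log, bin_width_s):
        n_pokes = sum(1 for e in pokes if lo <= e.timestamp < hi)
        n_pellets = sum(1 for e in pellets if lo <= e.timestamp < hi)
        rows.append(
            {
                "bin_start": lo,
                "pokes_per_pellet": n_pokes / n_pellets if n_pellets else float("nan"),
                "n_pokes": n_pokes,
                "n_pellets": n_pellets,
            }
        )
    return pd.DataFrame(rows)


def breakpoint(log: SessionLog, task: TaskSpec) -> tuple[int, list[int]]:
    """Progressive-ratio breakpoint by replaying the schedule on the log.

    The completed ratio of each pellet equals the number of operant
    active-port pokes since the previous pellet (pokes made while the
    pellet sat in the well are flagged non-operant and never count).  For
    closed-economy sessions a poke-free pause of at least
    ``task.reset_timeout`` seconds closes the bout and resets the ratio;
    the pause is measured between consecutive logged pokes, and a pause
    ending on a non-operant poke (pellet still in the well) does not
    reset, mirroring the device rule.

    Returns ``(session_breakpoint, per_bout)`` where each bout's
    breakpoint is the highest ratio completed within it; the session
    breakpoint is the max over bouts, 0 when no pellet was earned.
    """
    bouts = replay_ratio_bouts(log, task)
    per_bout = [max(b) for b in bouts]
    return (max(per_bout) if per_bout else 0), per_bout


def replay_ratio_bouts(log: SessionLog, task: TaskSpec) -> list[list[int]]:
    """Completed ratios per bout, reconstructed from the event stream.

    This is the replay underlying :func:`breakpoint`; it reproduces the
    device's internal ratio trace exactly on any well-formed log.
    """
    if task.mode not in ("ProgressiveRatio", "ClosedEconomyPR"):
        raise ValueError(
            f"breakpoint requires a progressive-ratio task, got mode {task.mode!r}"
        )
    bouts: list[list[int]] = []
    bout: list[int] = []
    pokes_since_pellet = 0
    last_poke: Optional[datetime] = None
    for e in log.events:
        if e.is_poke:
            if (
                task.mode == "ClosedEconomyPR"
                and last_poke is not None
                and (e.timestamp - last_poke).total_seconds() >= task.reset_timeout
                and e.operant
            ):
                if bout:
                    bouts.append(bout)
                    bout = []
                pokes_since_pellet = 0
            last_poke = e.timestamp
            if e.operant and e.is_active_poke:
                pokes_since_pellet += 1
        elif e.event_kind == "Pellet":
            bout.append(pokes_since_pellet)
            pokes_since_pellet = 0
    if bout:
        bouts.append(bout)
    return bouts


def dispensed_mass(log: SessionLog) -> float:
    """Grams of food dispensed: pellet count x pellet mass / 1000."""
    if log.pellet_mass_mg is None or log.pellet_mass_mg <= 0:
        raise ValueError("log has no valid pellet_mass_mg")
    return log.n_pellets * log.pellet_mass_mg / 1000.0
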