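"""Time-of-day binning: chronograms, day/night splits, hourly series.

A *chronogram* is the 24-h profile of a behavioral measure averaged across
recording days (and, for groups, across subjects).  Two alignments are
supported: ``clock`` keys bins by wall-clock hour; ``phase`` shifts each
log so that bin 0 corresponds to lights-on before averaging, which lets
logs recorded under different light schedules be pooled without smearing
the light/dark transition.

Per-day means use only *complete* 24-h spans counted from the recording
start; a partial trailing day is excluded so every time-of-day bin is
sampled the same number of times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .event_log import Event, LightCycle, SessionLog

__all__ = [
    "Chronogram",
    "VALUES",
    "assign_phase",
    "chronogram",
    "day_night_totals",
    "pellets_per_hour_series",
    "daily_bin_matrix",
]

VALUES = ("pellets", "active_pokes", "inactive_pokes", "pokes_per_pellet")


def assign_phase(t: datetime, light: LightCycle) -> str:
    """``"light"`` iff the clock time of ``t`` is in [lights_on, lights_off)."""
    return "light" if light.is_light(t) else "dark"


@dataclass(frozen=True)
class Chronogram:
    """Mean ± SEM of a measure per time-of-day bin, averaged over logs."""

    bin_width: float  # hours
    values: np.ndarray  # per-bin mean over logs
    dispersion: np.ndarray  # per-bin SEM over logs (0 when n == 1)
    n: int  # logs averaged
    alignment: str  # "clock" | "phase"

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        label = "hour" if self.alignment == "clock" else "hours_after_lights_on"
        return pd.DataFrame(
            {
                label: np.arange(self.n_bins) * self.bin_width,
                "mean": self.values,
                "sem": self.dispersion,
            }
        )


def _event_selector(value: str):
    if value == "pellets":
        return lambda e: e.event_kind == "Pellet"
    if value == "active_pokes":
        return lambda e: e.is_active_poke
    if value == "inactive_pokes":
        return lambda e: e.is_poke and not e.is_active_poke
    raise ValueError(f"unknown value {value!r}; expected one of {VALUES}")


def _complete_days(log: SessionLog):
    """(start, n_days): the whole-day window used for per-day means.

    Complete 24-h spans are counted from the recording start; a partial
    trailing day is excluded.  Because bins are keyed by clock time (or
    phase) modulo 24 h, the window itself need not start at midnight.
    """
    start, end = log.span()
    n_days = int((end - start).total_seconds() // 86400)
    return start, max(n_days, 0)


def _clock_hours(t: datetime) -> float:
    return t.hour + t.minute / 60 + t.second / 3600 + t.microsecond / 3.6e9


def daily_bin_matrix(
    log: SessionLog,
    value: str,
    light: Optional[LightCycle] = None,
    *,
    alignment: str = "clock",
    bin_width: float = 1.0,
) -> np.ndarray:
    """Counts per (complete day x time-of-day bin); the matrix behind a heatmap.

    ``value`` must be a count measure (``pellets``/``active_pokes``/
    ``inactive_pokes``).  Rows are consecutive complete days of the
    recording; columns are the ``24 / bin_width`` time-of-day bins, keyed
    by wall-clock hour (``clock``) or hours after lights-on (``phase``).
    """
    cycle = light or log.light_cycle
    n_bins = _check_bins(bin_width)
    if alignment not in ("clock", "phase"):
        raise ValueError(f"alignment must be 'clock' or 'phase', got {alignment!r}")
    select = _event_selector(value)
    anchor, n_days = _complete_days(log)
    if n_days == 0:
        raise ValueError("log contains no complete 24-h day for per-day means")
    mat = np.zeros((n_days, n_bins))
    for e in log.events:
        if not select(e):
            continue
        off = (e.timestamp - anchor).total_seconds()
        if not (0 <= off < n_days * 86400):
            continue
        h = _clock_hours(e.timestamp)
        if alignment == "phase":
            h = (h - cycle.lights_on) % 24.0
        mat[int(off // 86400.0), int(h // bin_width)] += 1
    return mat


def _check_bins(bin_width: float) -> int:
    n_bins = 24.0 / bin_width
    if bin_width <= 0 or abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must evenly divide 24 hours")
    return int(round(n_bins))


def chronogram(
    logs: Sequence[SessionLog],
    value: str = "pellets",
    light: Optional[LightCycle] = None,
    *,
    alignment: str = "clock",
    bin_width: float = 1.0,
) -> Chronogram:
    """Per-day mean of ``value`` per time-of-day bin, averaged across logs.

    For count measures each log contributes its per-day mean per bin (counts
    over complete days divided by the number of complete days).  For
    ``pokes_per_pellet`` each log contributes per-bin poke sum / pellet sum
    (NaN where no pellets fell in the bin; NaNs are ignored in the group
    mean).  Output is mean ± SEM across logs; SEM is 0 when only one log is
    given.
    """
    if not logs:
        raise ValueError("need at least one log")
    n_bins = _check_bins(bin_width)
    per_log = np.full((len(logs), n_bins), np.nan)
    for i, log in enumerate(logs):
        cycle = light or log.light_cycle
        if value == "pokes_per_pellet":
            pokes = daily_bin_matrix(
                log, "active_pokes", cycle, alignment=alignment, bin_width=bin_width
            ) + daily_bin_matrix(
                log, "inactive_pokes", cycle, alignment=alignment, bin_width=bin_width
            )
            pellets = daily_bin_matrix(
                log, "pellets", cycle, alignment=alignment, bin_width=bin_width
            )
            poke_sum = pokes.sum(axis=0)
            pellet_sum = pellets.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                per_log[i] = np.where(pellet_sum > 0, poke_sum / pellet_sum, np.nan)
        else:
            mat = daily_bin_matrix(
                log, value, cycle, alignment=alignment, bin_width=bin_width
            )
            per_log[i] = mat.sum(axis=0) / mat.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_log, axis=0)
        n_eff = np.sum(~np.isnan(per_log), axis=0)
        sd = np.nanstd(per_log, axis=0, ddof=1)
    sem = np.where(n_eff > 1, sd / np.sqrt(np.maximum(n_eff, 1)), 0.0)
    return Chronogram(
        bin_width=bin_width,
        values=mean,
        dispersion=sem,
        n=len(logs),
        alignment=alignment,
    )


def day_night_totals(
    log: SessionLog,
    value: str = "pellets",
    light: Optional[LightCycle] = None,
) -> pd.Series:
    """Per-day event counts in the dark vs light phase.

    Counts over complete (phase-anchored) days divided by the number of
    those days; ``dark + light`` equals the overall per-day mean.  Returns
    a Series indexed by ``dark``/``light``.
    """
    cycle = light or log.light_cycle
    select = _event_selector(value)
    anchor, n_days = _complete_days(log)
    if n_days == 0:
        raise ValueError("log contains no complete 24-h day for per-day means")
    dark = lit = 0
    for e in log.events:
        off = (e.timestamp - anchor).total_seconds()
        if not select(e) or not (0 <= off < n_days * 86400):
            continue
        if cycle.is_light(e.timestamp):
            lit += 1
        else:
            dark += 1
    return pd.Series(
        {"dark": dark / n_days, "light": lit / n_days}, name=f"{value}_per_day"
    )


def pellets_per_hour_series(log: SessionLog) -> pd.Series:
    """Contiguous hourly pellet counts from the first to the last event hour.

    Empty for an empty log; the series sum equals the total pellet count.
    """
    times = [e.timestamp for e in log.events]
    if not times:
        return pd.Series(dtype=int)
    first = times[0].replace(minute=0, second=0, microsecond=0)
    last = times[-1].replace(minute=0, second=0, microsecond=0)
    index = pd.date_range(first, last, freq="h")
    counts = pd.Series(0, index=index, dtype=int)
    for t in log.pellet_times:
        counts[t.replace(minute=0, second=0, microsecond=0)] += 1
    return counts
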