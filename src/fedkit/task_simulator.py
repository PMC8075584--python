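"""Discrete-event simulation of home-cage feeding/operant tasks.

The device side is a small state machine (pellet well, ratio counter,
pulse-train generator); the mouse side is a generative model with a
circadian nose-poke process, an accuracy learning curve, a retrieval-delay
distribution that shrinks with experience, and a bout-structured feeding
process.  Coupled together they produce event logs with the qualitative
structure of real recordings: nocturnal intake, meal clustering, rising
poke efficiency and falling retrieval times over the first hours of
operant training.

Task modes
----------
``FreeFeeding``
    A pellet sits in the well; each removal is logged and the next pellet
    is immediately available.  Nose-pokes have no consequence and are
    logged with ``operant=False``.
``TimeRestricted``
    Free feeding gated by a daily feeding window; outside the window the
    device neither dispenses nor rewards.
``FR1`` / ``ProgressiveRatio`` / ``ClosedEconomyPR``
    Pellets are earned by poking the active port.  FR1 requires one poke
    per pellet; PR increases the requirement after each earned pellet;
    closed-economy PR additionally resets the requirement to 1 after a
    poke-free pause of ``reset_timeout`` seconds (default 30 min).
    While a pellet occupies the well both pokes are inactive and are
    logged with ``operant=False``.
``SelfStim``
    Each active poke triggers a pulse train (default 1 s of 20 Hz); the
    session ends once ``max_trains`` trains (default 75) are delivered.
    Pokes during an ongoing train do not retrigger and are logged
    ``operant=False``.

Time handling: the simulation clock is continuous (event-driven); the
30-min closed-economy reset rule and the written log both operate on
timestamps quantized to 1 s, so an offline replay of the log reconstructs
the device state exactly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .event_log import Event, LightCycle, SessionLog

__all__ = [
    "RatioSchedule",
    "PulseTrainSpec",
    "TaskSpec",
    "MouseModel",
    "DeviceState",
    "MODES",
    "next_ratio",
    "apply_reset",
    "generate_pulse_train",
    "feeding_window_gate",
    "simulate_session",
    "export_pulse_waveform",
]

MODES = (
    "FreeFeeding",
    "TimeRestricted",
    "FR1",
    "ProgressiveRatio",
    "ClosedEconomyPR",
    "SelfStim",
)

RATIO_MODES = ("FR1", "ProgressiveRatio", "ClosedEconomyPR")


@dataclass(frozen=True)
class RatioSchedule:
    """Progression of the poke requirement across earned pellets.

    ``linear`` yields 1, 2, 3, ...  ``exponential`` yields
    ``round(a * exp(b * (completed + 1)) - a)`` clamped to >= 1, a standard
    progressive-ratio escalation (defaults a=5, b=0.2).
    """

    style: str = "linear"
    a: float = 5.0
    b: float = 0.2

    def __post_init__(self):
        if self.style not in ("linear", "exponential"):
            raise ValueError(f"unknown ratio schedule style {self.style!r}")


def next_ratio(schedule: RatioSchedule, completed: int) -> int:
    """Poke requirement for the (completed+1)-th pellet of a bout."""
    if completed < 0:
        raise ValueError("completed must be non-negative")
    if schedule.style == "linear":
        return completed + 1
    return max(1, round(schedule.a * math.exp(schedule.b * (completed + 1)) - schedule.a))


@dataclass(frozen=True)
class PulseTrainSpec:
    """A train of square pulses on the synchronization output."""

    frequency: float = 20.0  # Hz
    train_duration: float = 1.0  # s
    pulse_width: float = 0.005  # s
    amplitude: float = 3.3  # volts

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.train_duration < 0:
            raise ValueError("train_duration must be >= 0")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be > 0")
        if self.pulse_width >= 1.0 / self.frequency:
            raise ValueError("pulse_width must be < 1/frequency (pulses would overlap)")
        if not (0 <= self.amplitude <= 3.3):
            raise ValueError("amplitude must be within the 0-3.3 V output range")


def generate_pulse_train(spec: PulseTrainSpec, trigger_time: datetime) -> list[datetime]:
    """Pulse onsets at ``trigger_time + k/frequency`` while ``k/f < duration``."""
    onsets = []
    k = 0
    while k / spec.frequency < spec.train_duration:
        onsets.append(trigger_time + timedelta(seconds=k / spec.frequency))
        k += 1
    return onsets


@dataclass(frozen=True)
class TaskSpec:
    """A task mode plus its parameters."""

    mode: str = "FreeFeeding"
    active_port: str = "Left"
    ratio: RatioSchedule = field(default_factory=RatioSchedule)
    reset_timeout: float = 1800.0  # s, ClosedEconomyPR
    feeding_window: Optional[tuple[float, float]] = None  # clock hours, TimeRestricted
    train: PulseTrainSpec = field(default_factory=PulseTrainSpec)
    max_trains: int = 75  # SelfStim session cap
    cue_hz: float = 4000.0
    cue_s: float = 0.3

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown task mode {self.mode!r}")
        if self.active_port not in ("Left", "Right"):
            raise ValueError(f"active_port must be Left or Right, got {self.active_port!r}")
        if self.reset_timeout <= 0:
            raise ValueError("reset_timeout must be > 0")
        if self.max_trains < 1:
            raise ValueError("max_trains must be >= 1")
        if self.mode == "TimeRestricted":
            if self.feeding_window is None:
                raise ValueError("TimeRestricted requires a feeding_window")
            lo, hi = self.feeding_window
            if not (0 <= lo < 24 and 0 <= hi < 24):
                raise ValueError("feeding_window hours must be in [0, 24)")


def feeding_window_gate(now: datetime, window: tuple[float, float]) -> bool:
    """True iff the clock time of ``now`` is inside ``[start, end)``.

    Wraps across midnight when start > end (e.g. a (19, 7) window is open
    overnight).
    """
    lo, hi = window
    if not (0 <= lo < 24 and 0 <= hi < 24):
        raise ValueError("feeding_window hours must be in [0, 24)")
    h = now.hour + now.minute / 60 + now.second / 3600 + now.microsecond / 3.6e9
    if lo < hi:
        return lo <= h < hi
    return h >= lo or h < hi


@dataclass
class DeviceState:
    """Mutable device-side state during a ratio-schedule session."""

    pellet_in_well: bool = False
    current_ratio: int = 1
    pokes_toward_ratio: int = 0
    last_poke_time: Optional[datetime] = None
    trains_delivered: int = 0
    completed_in_bout: int = 0


def apply_reset(state: DeviceState, now: datetime, task: TaskSpec) -> DeviceState:
    """Closed-economy rule: a >= ``reset_timeout`` pause resets the ratio to 1.

    The boundary is inclusive (a pause of exactly the timeout resets).
    Returns the (mutated) state for convenience.
    """
    if task.mode != "ClosedEconomyPR":
        raise ValueError("apply_reset only applies to ClosedEconomyPR tasks")
    if (
        state.last_poke_time is not None
        and (now - state.last_poke_time).total_seconds() >= task.reset_timeout
    ):
        state.current_ratio = 1
        state.pokes_toward_ratio = 0
        state.completed_in_bout = 0
    return state


@dataclass(frozen=True)
class MouseModel:
    """Generative virtual-mouse parameters.

    Nose-pokes follow a piecewise-homogeneous Poisson process with separate
    dark/light rates (pokes/hour); setting ``poke_interval_s`` replaces the
    Poisson process with exactly periodic pokes (useful for hand-checkable
    fixtures).  Each poke lands on the active port with probability
    ``accuracy(t) = asymptote - (asymptote - start) * exp(-t / tau)`` where
    ``t`` is cumulative task exposure in hours.  Retrieval delays are
    log-normal with a median that decays with exposure on the same
    functional form.  Feeding in free-feeding modes is bout-structured:
    meal onsets arrive with exponential between-meal gaps (phase-dependent
    mean), meal sizes are 1 + Poisson(mean - 1) pellets, and within-meal
    removals have exponential gaps.

    Identical (task, mouse, start, duration, light) with the same ``seed``
    reproduces the log byte-for-byte.
    """

    poke_rate_dark: float = 60.0  # pokes/hour
    poke_rate_light: float = 20.0
    poke_interval_s: Optional[float] = None  # deterministic override
    accuracy_start: float = 0.5
    accuracy_asymptote: float = 0.85
    accuracy_tau_h: float = 4.0
    prior_exposure_h: float = 0.0
    retrieval_median_start_s: float = 30.0
    retrieval_median_asymptote_s: float = 3.0
    retrieval_tau_h: float = 4.0
    retrieval_sigma: float = 0.8
    within_meal_interval_s: float = 15.0
    meal_size_mean: float = 6.0
    between_meal_interval_dark_s: float = 2700.0
    between_meal_interval_light_s: float = 7200.0
    seed: int = 0

    def __post_init__(self):
        for name in ("accuracy_start", "accuracy_asymptote"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in (
            "poke_rate_dark",
            "poke_rate_light",
            "retrieval_median_start_s",
            "retrieval_median_asymptote_s",
            "retrieval_sigma",
            "prior_exposure_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "accuracy_tau_h",
            "retrieval_tau_h",
            "within_meal_interval_s",
            "between_meal_interval_dark_s",
            "between_meal_interval_light_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.meal_size_mean < 1:
            raise ValueError("meal_size_mean must be >= 1 pellet")
        if self.poke_interval_s is not None and self.poke_interval_s <= 0:
            raise ValueError("poke_interval_s must be > 0")

    def accuracy(self, exposure_h: float) -> float:
        t = exposure_h + self.prior_exposure_h
        return self.accuracy_asymptote - (
            self.accuracy_asymptote - self.accuracy_start
        ) * math.exp(-t / self.accuracy_tau_h)

    def retrieval_median(self, exposure_h: float) -> float:
        t = exposure_h + self.prior_exposure_h
        return self.retrieval_median_asymptote_s + (
            self.retrieval_median_start_s - self.retrieval_median_asymptote_s
        ) * math.exp(-t / self.retrieval_tau_h)


# ---------------------------------------------------------------------------
# Generative processes


def _phase_segments(
    start: datetime, duration: float, light: LightCycle
) -> list[tuple[float, float, bool]]:
    """(t0, t1, is_light) segments in seconds from ``start`` covering [0, duration)."""
    if duration <= 0:
        return []
    bounds = {0.0, duration}
    day0 = start.replace(hour=0, minute=0, second=0, microsecond=0)
    n_days = int(duration // 86400) + 2
    for d in range(-1, n_days + 1):
        for hour in (light.lights_on, light.lights_off):
            t = (day0 + timedelta(days=d, hours=hour) - start).total_seconds()
            if 0 < t < duration:
                bounds.add(t)
    edges = sorted(bounds)
    segments = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = start + timedelta(seconds=(lo + hi) / 2)
        segments.append((lo, hi, light.is_light(mid)))
    return segments


def _poke_times(
    mouse: MouseModel,
    start: datetime,
    duration: float,
    light: LightCycle,
    rng: np.random.Generator,
) -> np.ndarray:
    """Nose-poke times (seconds from start), sorted."""
    if mouse.poke_interval_s is not None:
        return np.arange(0.0, duration, mouse.poke_interval_s)
    times: list[np.ndarray] = []
    for lo, hi, is_light in _phase_segments(start, duration, light):
        rate = mouse.poke_rate_light if is_light else mouse.poke_rate_dark
        lam = rate * (hi - lo) / 3600.0
        n = rng.poisson(lam)
        if n:
            times.append(np.sort(rng.uniform(lo, hi, n)))
    if not times:
        return np.array([])
    return np.concatenate(times)


def _meal_pellet_times(
    mouse: MouseModel,
    start: datetime,
    duration: float,
    light: LightCycle,
    rng: np.random.Generator,
) -> tuple[list[float], list[tuple[float, int]]]:
    """Bout-structured pellet-removal attempt times.

    Returns (attempt times, generated meals as (onset_s, n_pellets)).
    """
    attempts: list[float] = []
    meals: list[tuple[float, int]] = []
    t = 0.0
    while True:
        phase_light = light.is_light(start + timedelta(seconds=min(t, duration)))
        mean_gap = (
            mouse.between_meal_interval_light_s
            if phase_light
            else mouse.between_meal_interval_dark_s
        )
        t = t + rng.exponential(mean_gap)
        if t >= duration:
            break
        size = 1 + rng.poisson(mouse.meal_size_mean - 1.0)
        onset = t
        emitted = 0
        for i in range(size):
            if i > 0:
                t = t + rng.exponential(mouse.within_meal_interval_s)
            if t >= duration:
                break
            attempts.append(t)
            emitted += 1
        if emitted:
            meals.append((onset, emitted))
        if t >= duration:
            break
    return attempts, meals


# ---------------------------------------------------------------------------
# Session simulation


class _LogBuilder:
    """Accumulates events in chronological order with cumulative counters."""

    def __init__(self, start: datetime, active_port: str):
        self.start = start
        self.active_port = active_port
        self.events: list[Event] = []
        self.left = 0
        self.right = 0
        self.pellets = 0

    def _stamp(self, t: float) -> datetime:
        return self.start + timedelta(seconds=int(t))

    def poke(self, t: float, port: str, operant: bool) -> None:
        if port == "Left":
            self.left += 1
        else:
            self.right += 1
        self.events.append(
            Event(
                timestamp=self._stamp(t),
                event_kind=f"{port}Poke",
                active_poke=self.active_port,
                left_count=self.left,
                right_count=self.right,
                pellet_count=self.pellets,
                operant=operant,
            )
        )

    def pellet(self, t: float, retrieval_time: float) -> None:
        self.pellets += 1
        self.events.append(
            Event(
                timestamp=self._stamp(t),
                event_kind="Pellet",
                active_poke=self.active_port,
                left_count=self.left,
                right_count=self.right,
                pellet_count=self.pellets,
                retrieval_time=round(float(retrieval_time), 2),
            )
        )


def _draw_delay(mouse: MouseModel, exposure_h: float, rng: np.random.Generator) -> float:
    median = mouse.retrieval_median(exposure_h)
    if median <= 0:
        return 0.0
    if mouse.retrieval_sigma == 0:
        return median
    return median * math.exp(mouse.retrieval_sigma * rng.standard_normal())


def _other(port: str) -> str:
    return "Right" if port == "Left" else "Left"


def simulate_session(
    task: TaskSpec,
    mouse: MouseModel,
    start: datetime,
    duration: float,
    light: Optional[LightCycle] = None,
    *,
    device_id: int = 0,
    pellet_mass_mg: float = 20.0,
    return_trace: bool = False,
):
    """Run one session and return its :class:`SessionLog`.

    ``duration`` is in seconds; the session covers ``[start, start +
    duration)``.  With ``return_trace=True`` also returns a dict exposing
    the simulator's internal ground truth: ``meals`` (free-feeding modes,
    list of (onset_s, n_pellets)), ``bouts`` (ratio modes, completed
    ratios per closed-economy bout), and ``trains`` (self-stim trigger
    times in seconds).  Analysis code never sees the trace; it exists so
    tests can compare log-replay estimates against the generating state.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    light = light or LightCycle()
    rng = np.random.default_rng(mouse.seed)
    builder = _LogBuilder(start, task.active_port)
    trace: dict = {"meals": [], "bouts": [], "trains": []}

    if task.mode in ("FreeFeeding", "TimeRestricted"):
        _run_free_feeding(task, mouse, start, duration, light, rng, builder, trace)
    elif task.mode in RATIO_MODES:
        _run_ratio_task(task, mouse, start, duration, light, rng, builder, trace)
    elif task.mode == "SelfStim":
        _run_self_stim(task, mouse, start, duration, light, rng, builder, trace)
        if len(trace["trains"]) >= task.max_trains:
            # the session terminates at the final train, not the nominal end
            duration = min(duration, int(trace["trains"][-1]) + 1)

    log = SessionLog(
        device_id=device_id,
        session_type=task.mode,
        light_cycle=light,
        pellet_mass_mg=pellet_mass_mg,
        events=builder.events,
        start_time=start,
        end_time=start + timedelta(seconds=int(duration)),
    )
    log.validate()
    if return_trace:
        return log, trace
    return log


def _window_open(task: TaskSpec, t_abs: datetime) -> bool:
    if task.mode != "TimeRestricted" or task.feeding_window is None:
        return True
    return feeding_window_gate(t_abs, task.feeding_window)


def _run_free_feeding(task, mouse, start, duration, light, rng, builder, trace):
    attempts, meals = _meal_pellet_times(mouse, start, duration, light, rng)
    pokes = _poke_times(mouse, start, duration, light, rng)
    trace["meals"] = meals

    # Merge pellet-removal attempts and (non-contingent) pokes in time order.
    stream = [(t, "attempt") for t in attempts] + [(t, "poke") for t in pokes]
    stream.sort(key=lambda x: x[0])
    available = 0.0  # time the current pellet became available
    for t, kind in stream:
        t_abs = start + timedelta(seconds=t)
        if kind == "poke":
            exposure_h = t / 3600.0
            port = (
                task.active_port
                if rng.random() < mouse.accuracy(exposure_h)
                else _other(task.active_port)
            )
            builder.poke(t, port, operant=False)
            continue
        if not _window_open(task, t_abs):
            continue
        if t < available:
            continue
        builder.pellet(t, retrieval_time=t - available)
        available = t
    # In the time-restricted mode some generated attempts are gated away;
    # recompute the realized meal structure is the analyzers' job, so the
    # trace keeps the generated meals only for the ungated mode.
    if task.mode == "TimeRestricted":
        trace["meals"] = []


def _run_ratio_task(task, mouse, start, duration, light, rng, builder, trace):
    pokes = _poke_times(mouse, start, duration, light, rng)
    state = DeviceState(current_ratio=1 if task.mode == "FR1" else next_ratio(task.ratio, 0))
    pending_removal: Optional[float] = None  # continuous time of pellet removal
    pending_ratio: Optional[int] = None
    bout: list[int] = []
    last_poke_logged: Optional[int] = None

    def flush_pellet(upto: float) -> None:
        nonlocal pending_removal, pending_ratio
        if pending_removal is not None and pending_removal < upto:
            builder.pellet(pending_removal, retrieval_time=pending_removal - dispense_time[0])
            bout.append(pending_ratio)
            pending_removal = None
            pending_ratio = None
            state.pellet_in_well = False

    dispense_time = [0.0]
    for t in pokes:
        flush_pellet(t)
        logged = int(t)
        if task.mode == "ClosedEconomyPR":
            if (
                last_poke_logged is not None
                and logged - last_poke_logged >= task.reset_timeout
                and not state.pellet_in_well
            ):
                if bout:
                    trace["bouts"].append(bout[:])
                    bout.clear()
                state.current_ratio = 1
                state.pokes_toward_ratio = 0
                state.completed_in_bout = 0
        last_poke_logged = logged
        exposure_h = t / 3600.0
        active = rng.random() < mouse.accuracy(exposure_h)
        port = task.active_port if active else _other(task.active_port)
        if state.pellet_in_well:
            builder.poke(t, port, operant=False)
            continue
        builder.poke(t, port, operant=True)
        if not active:
            continue
        state.pokes_toward_ratio += 1
        if state.pokes_toward_ratio >= state.current_ratio:
            # dispense; removal after the retrieval delay
            delay = _draw_delay(mouse, exposure_h, rng)
            removal = t + delay
            completed_ratio = state.current_ratio
            state.completed_in_bout += 1
            state.pokes_toward_ratio = 0
            if task.mode == "FR1":
                state.current_ratio = 1
            else:
                state.current_ratio = next_ratio(task.ratio, state.completed_in_bout)
            # the pellet occupies the well until removed, even if removal
            # would fall after session end (then no Pellet event is logged)
            state.pellet_in_well = True
            dispense_time[0] = t
            pending_removal = removal
            pending_ratio = completed_ratio
    flush_pellet(duration)
    if bout:
        trace["bouts"].append(bout)
    if task.mode != "ClosedEconomyPR":
        # single uninterrupted bout
        trace["bouts"] = [b for b in trace["bouts"] if b]


def _run_self_stim(task, mouse, start, duration, light, rng, builder, trace):
    pokes = _poke_times(mouse, start, duration, light, rng)
    trains = 0
    train_end = -math.inf
    for t in pokes:
        exposure_h = t / 3600.0
        active = rng.random() < mouse.accuracy(exposure_h)
        port = task.active_port if active else _other(task.active_port)
        if active and t >= train_end:
            builder.poke(t, port, operant=True)
            trains += 1
            trace["trains"].append(t)
            train_end = t + task.train.train_duration
            if trains >= task.max_trains:
                break
        else:
            # active pokes during an ongoing train do not retrigger
            blocked = active and t < train_end
            builder.poke(t, port, operant=not blocked)


def export_pulse_waveform(
    spec: PulseTrainSpec, trigger_times_s: list[float], path: str
) -> None:
    """Write the output-line voltage waveform as two-column CSV (time_s, volts).

    Each pulse contributes a rising edge at its onset and a falling edge
    ``pulse_width`` later, giving a step-function representation suitable
    for alignment against external recordings.
    """
    rows: list[tuple[float, float]] = []
    for trig in trigger_times_s:
        k = 0
        while k / spec.frequency < spec.train_duration:
            onset = trig + k / spec.frequency
            rows.append((onset, spec.amplitude))
            rows.append((onset + spec.pulse_width, 0.0))
            k += 1
    rows.sort(key=lambda r: r[0])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["time_s", "volts"])
        for t, v in rows:
            writer.writerow([repr(round(t, 6)), repr(v)])
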