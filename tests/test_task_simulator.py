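"""Task state machines and the generative mouse model."""

import math
from datetime import datetime, timedelta

import pytest

from fedkit.event_log import LightCycle, write_log
from fedkit.task_simulator import (
    DeviceState,
    MouseModel,
    PulseTrainSpec,
    RatioSchedule,
    TaskSpec,
    apply_reset,
    feeding_window_gate,
    generate_pulse_train,
    next_ratio,
    simulate_session,
)

from conftest import T0


def deterministic_mouse(**kw):
    base = dict(
        poke_interval_s=60.0,
        accuracy_start=1.0,
        accuracy_asymptote=1.0,
        retrieval_median_start_s=0.0,
        retrieval_median_asymptote_s=0.0,
        seed=1,
    )
    base.update(kw)
    return MouseModel(**base)


class TestNextRatio:
    @pytest.mark.parametrize("completed,expected", [(0, 1), (1, 2), (4, 5), (9, 10)])
    def test_linear(self, completed, expected):
        assert next_ratio(RatioSchedule("linear"), completed) == expected

    @pytest.mark.parametrize(
        "completed,expected",
        # round(5 * exp(0.2 * (completed + 1)) - 5), clamped to >= 1
        [(0, 1), (1, 2), (2, 4), (3, 6), (9, 32)],
    )
    def test_exponential_defaults(self, completed, expected):
        sched = RatioSchedule("exponential")
        assert next_ratio(sched, completed) == expected
        # cross-check against the closed form
        assert expected == max(1, round(5 * math.exp(0.2 * (completed + 1)) - 5))

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError):
            RatioSchedule("geometric")

    def test_negative_completed_rejected(self):
        with pytest.raises(ValueError):
            next_ratio(RatioSchedule(), -1)


class TestApplyReset:
    def _state(self, minutes_ago):
        return DeviceState(
            current_ratio=7,
            pokes_toward_ratio=3,
            last_poke_time=T0 - timedelta(minutes=minutes_ago),
        )

    def test_31_min_silence_resets(self):
        state = apply_reset(self._state(31), T0, TaskSpec(mode="ClosedEconomyPR"))
        assert state.current_ratio == 1 and state.pokes_toward_ratio == 0

    def test_29_min_silence_keeps_state(self):
        state = apply_reset(self._state(29), T0, TaskSpec(mode="ClosedEconomyPR"))
        assert state.current_ratio == 7 and state.pokes_toward_ratio == 3

    def test_exactly_30_min_resets_inclusive(self):
        state = apply_reset(self._state(30), T0, TaskSpec(mode="ClosedEconomyPR"))
        assert state.current_ratio == 1

    def test_wrong_mode_rejected(self):
        with pytest.raises(ValueError):
            apply_reset(self._state(31), T0, TaskSpec(mode="FR1"))


class TestPulseTrain:
    def test_20hz_1s_train(self):
        onsets = generate_pulse_train(PulseTrainSpec(frequency=20, train_duration=1), T0)
        assert len(onsets) == 20
        assert onsets[0] == T0
        gaps = {
            round((b - a).total_seconds(), 9) for a, b in zip(onsets[:-1], onsets[1:])
        }
        assert gaps == {0.05}

    def test_zero_duration_empty(self):
        assert generate_pulse_train(PulseTrainSpec(train_duration=0), T0) == []

    def test_fractional_duration(self):
        # brute force: onsets k/f with k/f < 2.5 at 1 Hz -> k = 0, 1, 2
        onsets = generate_pulse_train(
            PulseTrainSpec(frequency=1, train_duration=2.5, pulse_width=0.005), T0
        )
        assert [round((t - T0).total_seconds()) for t in onsets] == [0, 1, 2]

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PulseTrainSpec(frequency=20, pulse_width=0.06)

    def test_amplitude_range(self):
        with pytest.raises(ValueError):
            PulseTrainSpec(amplitude=5.0)


class TestFeedingWindow:
    @pytest.mark.parametrize(
        "hour,minute,expected",
        [(20, 0, True), (12, 0, False), (19, 0, True), (7, 0, False), (6, 59, True)],
    )
    def test_overnight_window(self, hour, minute, expected):
        now = datetime(2021, 1, 1, hour, minute)
        assert feeding_window_gate(now, (19.0, 7.0)) is expected

    def test_daytime_window_half_open(self):
        assert feeding_window_gate(datetime(2021, 1, 1, 9), (9.0, 17.0))
        assert not feeding_window_gate(datetime(2021, 1, 1, 17), (9.0, 17.0))


class TestSimulateSession:
    def test_fr1_hand_simulation(self):
        log = simulate_session(TaskSpec(mode="FR1"), deterministic_mouse(), T0, 600)
        kinds = [e.event_kind for e in log.events]
        assert kinds.count("LeftPoke") == 10
        assert kinds.count("Pellet") == 10
        assert all(e.operant for e in log.events)
        assert log.events[-1].pellet_count == 10

    def test_zero_duration_empty(self):
        log = simulate_session(TaskSpec(mode="FR1"), deterministic_mouse(), T0, 0)
        assert len(log) == 0

    def test_same_seed_byte_identical(self, tmp_path):
        task = TaskSpec(mode="ClosedEconomyPR")
        paths = []
        for name in ("a.csv", "b.csv"):
            log = simulate_session(task, MouseModel(seed=11), T0, 6 * 3600)
            write_log(log, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self):
        task = TaskSpec(mode="FR1")
        a = simulate_session(task, MouseModel(seed=1), T0, 6 * 3600)
        b = simulate_session(task, MouseModel(seed=2), T0, 6 * 3600)
        assert a.events != b.events

    def test_selfstim_caps_at_max_trains(self):
        task = TaskSpec(mode="SelfStim", max_trains=75)
        mouse = deterministic_mouse(poke_interval_s=2.0)
        log, trace = simulate_session(task, mouse, T0, 8 * 3600, return_trace=True)
        assert len(trace["trains"]) == 75
        active = sum(1 for e in log.events if e.is_active_poke and e.operant)
        assert active == 75
        # session terminated at the 75th train, well before nominal end
        assert log.end_time < T0 + timedelta(hours=8)

    def test_selfstim_refractory_pokes_flagged(self):
        # poking faster than the 1 s train duration: intervening active
        # pokes are logged but cannot retrigger
        task = TaskSpec(mode="SelfStim", max_trains=10)
        mouse = deterministic_mouse(poke_interval_s=0.4)
        log, trace = simulate_session(task, mouse, T0, 600, return_trace=True)
        assert len(trace["trains"]) == 10
        blocked = [e for e in log.events if e.is_active_poke and not e.operant]
        assert blocked  # some pokes landed during an ongoing train

    def test_pellet_blocks_pokes_until_removal(self):
        # 60 s retrieval delay, poke every 10 s: pokes while the pellet sits
        # in the well must be non-operant and earn nothing
        mouse = deterministic_mouse(
            poke_interval_s=10.0,
            retrieval_median_start_s=60.0,
            retrieval_median_asymptote_s=60.0,
            retrieval_sigma=0.0,
        )
        log = simulate_session(TaskSpec(mode="FR1"), mouse, T0, 600)
        pellets = [e for e in log.events if e.event_kind == "Pellet"]
        assert pellets
        blocked = [e for e in log.events if e.is_poke and not e.operant]
        assert blocked
        # FR1 accounting: every pellet corresponds to one operant active poke
        operant_active = [e for e in log.events if e.is_active_poke and e.operant]
        assert len(pellets) <= len(operant_active)

    def test_invalid_arguments_rejected_before_simulation(self):
        with pytest.raises(ValueError):
            simulate_session(TaskSpec(mode="FR1"), deterministic_mouse(), T0, -1)
        with pytest.raises(ValueError):
            MouseModel(accuracy_start=1.5)
        with pytest.raises(ValueError):
            TaskSpec(mode="TimeRestricted")  # no feeding window

    def test_time_restricted_pellets_only_in_window(self):
        task = TaskSpec(mode="TimeRestricted", feeding_window=(19.0, 7.0))
        mouse = MouseModel(seed=5)
        log = simulate_session(task, mouse, T0, 2 * 86400)
        for t in log.pellet_times:
            assert feeding_window_gate(t, (19.0, 7.0))

    def test_closed_economy_ratio_sequence_is_schedule_prefix(self):
        task = TaskSpec(mode="ClosedEconomyPR")
        mouse = MouseModel(poke_rate_dark=20.0, poke_rate_light=6.0, seed=9)
        _, trace = simulate_session(task, mouse, T0, 86400, return_trace=True)
        assert trace["bouts"]
        for bout in trace["bouts"]:
            assert bout == list(range(1, len(bout) + 1))

    def test_state_machine_safety_no_double_dispense(self):
        # between two consecutive pellet events there is at least one
        # operant active poke (the dispense-eligible poke sequence)
        task = TaskSpec(mode="FR1")
        log = simulate_session(task, MouseModel(seed=21), T0, 12 * 3600)
        since_last_pellet = None
        for e in log.events:
            if e.event_kind == "Pellet":
                if since_last_pellet is not None:
                    assert since_last_pellet >= 1
                since_last_pellet = 0
            elif e.is_active_poke and e.operant and since_last_pellet is not None:
                since_last_pellet += 1
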