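from datetime import datetime, timedelta

import pytest
from hypothesis import settings

from fedkit.event_log import Event, LightCycle, SessionLog

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

T0 = datetime(2021, 1, 1, 7, 0, 0)


def build_log(
    spec,
    start=T0,
    end=None,
    active_port="Left",
    session_type="FR1",
    light=None,
    pellet_mass_mg=20.0,
):
    """Construct a valid SessionLog from (offset_s, kind[, operant/retrieval]) tuples.

    ``spec`` items: (seconds_from_start, "L"|"R"|"P") or
    (seconds, kind, operant_flag) for pokes / (seconds, "P", retrieval_time)
    for pellets.  Cumulative counters are filled in automatically.
    """
    left = right = pellets = 0
    events = []
    for item in spec:
        off, kind = item[0], item[1]
        extra = item[2] if len(item) > 2 else None
        ts = start + timedelta(seconds=off)
        if kind == "P":
            pellets += 1
            events.append(
                Event(
                    timestamp=ts,
                    event_kind="Pellet",
                    active_poke=active_port,
                    left_count=left,
                    right_count=right,
                    pellet_count=pellets,
                    retrieval_time=extra if extra is not None else 1.0,
                )
            )
        else:
            port = "Left" if kind == "L" else "Right"
            if port == "Left":
                left += 1
            else:
                right += 1
            events.append(
                Event(
                    timestamp=ts,
                    event_kind=f"{port}Poke",
                    active_poke=active_port,
                    left_count=left,
                    right_count=right,
                    pellet_count=pellets,
                    operant=True if extra is None else extra,
                )
            )
    log = SessionLog(
        session_type=session_type,
        light_cycle=light or LightCycle(),
        pellet_mass_mg=pellet_mass_mg,
        events=events,
        start_time=start,
        end_time=end or (events[-1].timestamp + timedelta(seconds=1) if events else start),
    )
    log.validate()
    return log


@pytest.fixture
def t0():
    return T0


@pytest.fixture
def twelve_twelve():
    return LightCycle(7.0, 19.0)
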