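from datetime import datetime, time, timedelta

import numpy as np
import pytest

from circabox import (
    BoxSchedule,
    MouseParams,
    SchedulePhase,
    generate_light_trace,
    simulate_activity,
)

START = datetime(2024, 1, 1, 7, 0)


def ld_phase(on="07:00", off="19:00", T=24.0, start=START):
    on_h, on_m = map(int, on.split(":"))
    off_h, off_m = map(int, off.split(":"))
    return SchedulePhase(
        mode="LD", initiation=start, on_time=time(on_h, on_m),
        off_time=time(off_h, off_m), cycle_length_T=T,
    )


def dd_phase(start=START, T=24.0):
    return SchedulePhase(mode="DD", initiation=start, cycle_length_T=T)


def ld_trace(days=14, T=24.0, on="07:00", off="19:00", start=START):
    sched = BoxSchedule(1, [ld_phase(on=on, off=off, T=T, start=start)])
    end = start + timedelta(hours=T * 24 * days / 24)
    return generate_light_trace(sched, start, end)


def dd_trace(days=14, start=START):
    sched = BoxSchedule(1, [dd_phase(start=start)])
    return generate_light_trace(sched, start, start + timedelta(days=days))


@pytest.fixture(scope="session")
def entrained_sim():
    """Default mouse, 14 days of 12:12 LD at T = 24."""
    return simulate_activity(MouseParams(seed=42), ld_trace(days=14))


@pytest.fixture(scope="session")
def freerun_sim():
    """Strain-preset mouse free-running 14 days in constant darkness."""
    return simulate_activity(MouseParams(seed=42), dd_trace(days=14))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
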