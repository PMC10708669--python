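"""Multi-phase light-schedule engine with a T-cycle internal clock.

A schedule is a sequence of up to 12 phases per box. Each phase is LD
(alternating light-dark with ON/OFF clock times), DD (constant dark) or LL
(constant light), starts at an explicit calendar initiation time ("from"),
and may run on a cycle length T different from 24 h. Non-24-h cycles are
realised through an internal clock that advances at a rate of 24/T relative
to external (Unix) time:

    internal_time += 24/T * dt_external

so a 12:12 program written on the internal clock stretches to 12.5 h light /
12.5 h dark of external time when T = 25. ON/OFF times are compared against
the internal clock. At a phase's initiation the internal wall-clock is seeded
from the initiation's external clock time, which anchors light timing to the
"from" field (e.g. a DD-to-LL transition turns the light on exactly at the
initiation minute).

All times are naive datetimes interpreted on a fixed epoch (no DST).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timezone
from typing import Optional, Sequence

import numpy as np

SECONDS_PER_DAY = 86400
MAX_PHASES = 12
VALID_MODES = ("LD", "DD", "LL")


class ScheduleError(ValueError):
    """Raised for unusable schedules or queries outside their domain."""


def to_unix(dt: datetime) -> float:
    """Naive datetimes are treated as UTC; no DST adjustments ever apply."""
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def from_unix(ts: float) -> datetime:
    return datetime.fromtimestamp(ts, tz=timezone.utc).replace(tzinfo=None)


def _seconds_of_day(t: time) -> float:
    return t.hour * 3600 + t.minute * 60 + t.second


@dataclass(frozen=True)
class SchedulePhase:
    """One step of a light program.

    Parameters
    ----------
    mode : {"LD", "DD", "LL"}
    initiation : datetime
        External calendar time at which this phase takes over (minute
        resolution is typical; finer is accepted).
    on_time, off_time : datetime.time, optional
        Lights-on / lights-off clock times on the *internal* clock.
        Required for LD, ignored for DD/LL.
    cycle_length_T : float
        Cycle length T in hours (default 24.0). The internal clock runs at
        24/T times the external rate, so ON/OFF times recur every T external
        hours.
    """

    mode: str
    initiation: datetime
    on_time: Optional[time] = None
    off_time: Optional[time] = None
    cycle_length_T: float = 24.0

    def internal_clock_at(self, t_external: float) -> float:
        """Internal wall-clock (seconds of day) at external Unix time."""
        t0 = to_unix(self.initiation)
        seed = _seconds_of_day(self.initiation.time())
        return (seed + (24.0 / self.cycle_length_T) * (t_external - t0)) % SECONDS_PER_DAY


@dataclass(frozen=True)
class BoxSchedule:
    """An ordered light program (1-12 phases) for one box (id 1-5)."""

    box_id: int
    phases: tuple[SchedulePhase, ...]

    def __init__(self, box_id: int, phases: Sequence[SchedulePhase]):
        object.__setattr__(self, "box_id", box_id)
        object.__setattr__(self, "phases", tuple(phases))


@dataclass
class InternalClockState:
    """Accumulated internal time (seconds since phase initiation, on the
    T-scaled axis) together with the last external Unix time seen."""

    internal_time: float = 0.0
    last_external_time: float = 0.0


@dataclass(frozen=True)
class LightTrace:
    """LED state series (0/1) on a fixed external sampling grid."""

    start: datetime
    step: float  # seconds
    states: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "states", np.ascontiguousarray(np.asarray(self.states, dtype=np.uint8))
        )
        if self.states.size and not np.isin(self.states, (0, 1)).all():
            raise ValueError("LED states must be 0 or 1")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def duration_seconds(self) -> float:
        return len(self.states) * self.step

    def times_unix(self) -> np.ndarray:
        return to_unix(self.start) + self.step * np.arange(len(self.states))


def validate_schedule(schedule: BoxSchedule) -> list[str]:
    """Check every schedule invariant; return the violations (empty if valid).

    Violations are returned rather than raised so a UI or CLI can report all
    of them at once.
    """
    violations: list[str] = []
    if not 1 <= schedule.box_id <= 5:
        violations.append(f"box_id {schedule.box_id} outside 1-5")
    n = len(schedule.phases)
    if n == 0:
        violations.append("schedule has no phases")
    if n > MAX_PHASES:
        violations.append(f"phase count {n} exceeds {MAX_PHASES}")
    for i, ph in enumerate(schedule.phases):
        if ph.mode not in VALID_MODES:
            violations.append(f"phase {i}: unknown mode {ph.mode!r}")
        if not ph.cycle_length_T > 0:
            violations.append(f"phase {i}: cycle_length_T must be > 0")
        if ph.mode == "LD":
            if ph.on_time is None:
                violations.append(f"phase {i}: LD phase missing on_time")
            if ph.off_time is None:
                violations.append(f"phase {i}: LD phase missing off_time")
    for i in range(1, n):
        if schedule.phases[i].initiation <= schedule.phases[i - 1].initiation:
            violations.append(
                f"phase {i}: initiation not strictly after phase {i - 1}"
            )
    return violations


def advance_internal_clock(
    state: InternalClockState, phase: SchedulePhase, dt_external: float
) -> InternalClockState:
    """Advance the internal clock by one external sampling interval.

    The increment is (24 / T) * dt_external, so one full external T-cycle
    always accumulates exactly 24 internal hours.
    """
    if dt_external <= 0:
        raise ValueError(f"dt_external must be positive, got {dt_external}")
    return InternalClockState(
        internal_time=state.internal_time
        + (24.0 / phase.cycle_length_T) * dt_external,
        last_external_time=state.last_external_time + dt_external,
    )


def active_phase(
    schedule: BoxSchedule, t_external: datetime
) -> tuple[SchedulePhase, datetime]:
    """Return the governing phase at ``t_external`` and its initiation time.

    The governing phase is the one with the latest initiation <= t_external;
    a query exactly at an initiation belongs to that (later) phase. The
    returned initiation is the origin of the phase-local internal clock.
    """
    current = None
    for ph in schedule.phases:
        if ph.initiation <= t_external:
            current = ph
        else:
            break
    if current is None:
        raise ScheduleError(
            f"schedule not yet started at {t_external} "
            f"(first phase begins {schedule.phases[0].initiation})"
        )
    return current, current.initiation


def led_state(phase: SchedulePhase, internal_clock_seconds: float) -> int:
    """LED state (1 on, 0 off) for an internal wall-clock time in seconds.

    DD is always 0 and LL always 1. For LD the lit interval is half-open
    [on, off): when ON precedes OFF the light is on within the same internal
    day; when ON is after OFF the lit interval spans midnight (on through
    24:00, then 00:00 through off).
    """
    if phase.mode == "DD":
        return 0
    if phase.mode == "LL":
        return 1
    on = _seconds_of_day(phase.on_time)
    off = _seconds_of_day(phase.off_time)
    t = internal_clock_seconds % SECONDS_PER_DAY
    if on < off:
        return int(on <= t < off)
    if on > off:
        return int(t >= on or t < off)
    return 0  # degenerate on == off: empty lit interval


def _led_states_vector(phase: SchedulePhase, internal_secs: np.ndarray) -> np.ndarray:
    if phase.mode == "DD":
        return np.zeros(len(internal_secs), dtype=np.uint8)
    if phase.mode == "LL":
        return np.ones(len(internal_secs), dtype=np.uint8)
    on = _seconds_of_day(phase.on_time)
    off = _seconds_of_day(phase.off_time)
    t = internal_secs % SECONDS_PER_DAY
    if on < off:
        lit = (t >= on) & (t < off)
    elif on > off:
        lit = (t >= on) | (t < off)
    else:
        lit = np.zeros(len(t), dtype=bool)
    return lit.astype(np.uint8)


def generate_light_trace(
    schedule: BoxSchedule,
    start: datetime,
    end: datetime,
    step: float = 60.0,
) -> LightTrace:
    """Sample the LED state on a fixed grid from ``start`` (inclusive) to
    ``end`` (exclusive).

    Each sample finds the governing phase, evaluates that phase's internal
    clock at the sample's external time, and applies the ON/OFF rule. Phase
    changes mid-trace are honored; after the last phase its rules persist.
    """
    if not start < end:
        raise ScheduleError("start must precede end")
    violations = validate_schedule(schedule)
    if violations:
        raise ScheduleError("invalid schedule: " + "; ".join(violations))
    if start < schedule.phases[0].initiation:
        raise ScheduleError(
            f"trace start {start} precedes first phase initiation "
            f"{schedule.phases[0].initiation}"
        )
    n = int(round((to_unix(end) - to_unix(start)) / step))
    times = to_unix(start) + step * np.arange(n)
    states = np.zeros(n, dtype=np.uint8)
    # resolve phase ownership once per phase segment, then vectorize within it
    bounds = [to_unix(ph.initiation) for ph in schedule.phases] + [np.inf]
    for i, ph in enumerate(schedule.phases):
        sel = (times >= bounds[i]) & (times < bounds[i + 1])
        if not sel.any():
            continue
        t0 = to_unix(ph.initiation)
        seed = _seconds_of_day(ph.initiation.time())
        internal = seed + (24.0 / ph.cycle_length_T) * (times[sel] - t0)
        states[sel] = _led_states_vector(ph, internal)
    return LightTrace(start=start, step=step, states=states)


def dark_onset_shift(phase_a: SchedulePhase, phase_b: SchedulePhase) -> float:
    """Signed shift of the lights-off event between two LD phases, in hours.

    Positive is a delay: moving lights-off from 19:00 to 1:00 crosses
    midnight, is read as 25:00, and reports +6 h. The result is unwrapped
    into (-12, +12].
    """
    for name, ph in (("phase_a", phase_a), ("phase_b", phase_b)):
        if ph.mode != "LD":
            raise ScheduleError(f"dark-onset shift undefined for {name} mode {ph.mode}")
    off_a = _seconds_of_day(phase_a.off_time) / 3600.0
    off_b = _seconds_of_day(phase_b.off_time) / 3600.0
    shift = (off_b - off_a + 12.0) % 24.0 - 12.0
    if shift == -12.0:
        shift = 12.0
    return shift
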