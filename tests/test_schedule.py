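"""Schedule engine: validation, the T-scaled internal clock, LED rules."""

from datetime import datetime, time, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circabox import (
    BoxSchedule,
    InternalClockState,
    ScheduleError,
    SchedulePhase,
    active_phase,
    advance_internal_clock,
    dark_onset_shift,
    generate_light_trace,
    led_state,
    validate_schedule,
)
from conftest import START, dd_phase, ld_phase


class TestValidateSchedule:
    def test_minimal_dd_schedule_is_valid(self):
        assert validate_schedule(BoxSchedule(1, [dd_phase()])) == []

    def test_thirteen_phases_rejected(self):
        phases = [
            dd_phase(start=START + timedelta(days=i)) for i in range(13)
        ]
        violations = validate_schedule(BoxSchedule(1, phases))
        assert any("exceeds 12" in v for v in violations)

    def test_ld_missing_off_time_named(self):
        bad = SchedulePhase("LD", START, on_time=time(7), off_time=None)
        violations = validate_schedule(BoxSchedule(1, [bad]))
        assert violations == ["phase 0: LD phase missing off_time"]

    def test_duplicate_initiations_rejected(self):
        violations = validate_schedule(BoxSchedule(1, [dd_phase(), dd_phase()]))
        assert any("not strictly after" in v for v in violations)

    @pytest.mark.parametrize("box_id", [0, 6])
    def test_box_id_range(self, box_id):
        assert validate_schedule(BoxSchedule(box_id, [dd_phase()]))


class TestInternalClock:
    @pytest.mark.parametrize(
        "T,dt,expected",
        [(24.0, 60.0, 60.0), (25.0, 60.0, 57.6), (12.0, 60.0, 120.0)],
    )
    def test_advance_scales_by_24_over_T(self, T, dt, expected):
        state = InternalClockState()
        state = advance_internal_clock(state, dd_phase(T=T), dt)
        assert state.internal_time == pytest.approx(expected, abs=1e-12)
        assert state.last_external_time == dt

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            advance_internal_clock(InternalClockState(), dd_phase(), 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(T=st.floats(min_value=0.5, max_value=100.0, allow_nan=False))
    def test_one_external_cycle_accumulates_24_internal_hours(self, T):
        """Closed-form consequence of the update rule, any T > 0."""
        state = InternalClockState()
        state = advance_internal_clock(state, dd_phase(T=T), T * 3600.0)
        assert state.internal_time / 3600.0 == pytest.approx(24.0, rel=1e-12)

    @pytest.mark.parametrize("T", [12.0, 24.0, 24.7, 25.0])
    def test_sampled_cycle_accumulates_24_hours(self, T):
        """Stepping minute by minute across one full T-cycle gives 24 h."""
        state = InternalClockState()
        phase = dd_phase(T=T)
        for _ in range(int(round(T * 60))):
            state = advance_internal_clock(state, phase, 60.0)
        assert state.internal_time / 3600.0 == pytest.approx(24.0, rel=1e-9)


class TestActivePhase:
    def two_phase(self):
        return BoxSchedule(
            1, [dd_phase(start=START), dd_phase(start=START + timedelta(days=9))]
        )

    def test_interval_membership(self):
        ph, origin = active_phase(self.two_phase(), START + timedelta(days=4))
        assert origin == START

    def test_boundary_owned_by_later_phase(self):
        sched = self.two_phase()
        ph, origin = active_phase(sched, START + timedelta(days=9))
        assert origin == START + timedelta(days=9)

    def test_before_first_initiation_raises(self):
        with pytest.raises(ScheduleError, match="not yet started"):
            active_phase(self.two_phase(), START - timedelta(minutes=1))

    def test_dd_to_ll_light_on_at_initiation(self):
        """A DD-to-LL transition turns the light on exactly at 'from'."""
        switch = START + timedelta(days=3, hours=2)
        sched = BoxSchedule(
            1,
            [dd_phase(start=START),
             SchedulePhase("LL", initiation=switch)],
        )
        trace = generate_light_trace(sched, START, switch + timedelta(hours=1))
        times = trace.times_unix()
        switch_idx = int((switch - START).total_seconds() // 60)
        assert trace.states[switch_idx - 1] == 0
        assert trace.states[switch_idx:].all()


class TestLedState:
    phase_day = ld_phase(on="07:00", off="19:00")
    phase_span = ld_phase(on="19:00", off="07:00")

    @pytest.mark.parametrize(
        "phase,clock_h,expected",
        [
            (phase_day, 12, 1),   # inside same-day lit interval
            (phase_day, 6, 0),
            (phase_day, 7, 1),    # half-open: on boundary lit
            (phase_day, 19, 0),   # half-open: off boundary dark
            (phase_span, 23, 1),  # spans midnight
            (phase_span, 3, 1),
            (phase_span, 12, 0),
        ],
    )
    def test_two_case_rule(self, phase, clock_h, expected):
        assert led_state(phase, clock_h * 3600.0) == expected

    def test_dd_always_dark_ll_always_lit(self):
        for h in range(24):
            assert led_state(dd_phase(), h * 3600.0) == 0
            assert led_state(SchedulePhase("LL", START), h * 3600.0) == 1

    def test_swapping_on_off_inverts_the_rule(self):
        """Same-day and midnight-spanning rules are complementary away
        from the boundary samples."""
        a = ld_phase(on="07:00", off="19:00")
        b = ld_phase(on="19:00", off="07:00")
        secs = np.arange(0, 86400, 60.0)
        sa = np.array([led_state(a, s) for s in secs])
        sb = np.array([led_state(b, s) for s in secs])
        assert (sa ^ sb).all()


class TestGenerateLightTrace:
    def test_12_12_day_has_720_lit_samples(self):
        sched = BoxSchedule(1, [ld_phase()])
        trace = generate_light_trace(sched, START, START + timedelta(hours=24))
        assert len(trace) == 1440
        assert int(trace.states.sum()) == 720

    def test_t24_trace_is_exactly_24h_periodic(self):
        sched = BoxSchedule(1, [ld_phase()])
        trace = generate_light_trace(sched, START, START + timedelta(days=5))
        days = trace.states.reshape(5, 1440)
        assert (days == days[0]).all()

    def test_t25_dilates_to_12_5_external_hours_of_light(self):
        """An internal 12:12 program under T = 25 spends 12.5 external
        hours lit and repeats every 25 external hours."""
        sched = BoxSchedule(1, [ld_phase(T=25.0)])
        trace = generate_light_trace(sched, START, START + timedelta(hours=50))
        cycle = trace.states[: 25 * 60]
        assert int(cycle.sum()) == int(12.5 * 60)
        assert (trace.states[25 * 60:] == cycle).all()

    @pytest.mark.parametrize("T", [24.0, 24.7, 25.0, 12.0])
    def test_lit_fraction_matches_internal_lit_hours(self, T):
        sched = BoxSchedule(1, [ld_phase(T=T)])
        n = int(round(T * 60))
        trace = generate_light_trace(
            sched, START, START + timedelta(hours=T)
        )
        assert trace.states[:n].mean() == pytest.approx(12.0 / 24.0, abs=1.0 / n)

    def test_half_step_agrees_on_shared_grid(self):
        sched = BoxSchedule(1, [ld_phase(T=24.7)])
        end = START + timedelta(hours=30)
        coarse = generate_light_trace(sched, START, end, step=60.0)
        fine = generate_light_trace(sched, START, end, step=30.0)
        assert (fine.states[::2] == coarse.states).all()

    def test_dd_trace_all_zero(self):
        sched = BoxSchedule(1, [dd_phase()])
        trace = generate_light_trace(sched, START, START + timedelta(days=2))
        assert not trace.states.any()

    def test_phase_change_honored_mid_trace(self):
        sched = BoxSchedule(
            1, [dd_phase(start=START),
                SchedulePhase("LL", initiation=START + timedelta(days=1))]
        )
        trace = generate_light_trace(sched, START, START + timedelta(days=2))
        assert not trace.states[:1440].any()
        assert trace.states[1440:].all()

    def test_invalid_schedule_raises(self):
        bad = BoxSchedule(1, [SchedulePhase("LD", START, on_time=time(7))])
        with pytest.raises(ScheduleError, match="invalid schedule"):
            generate_light_trace(bad, START, START + timedelta(days=1))


class TestDarkOnsetShift:
    @pytest.mark.parametrize(
        "off_a,off_b,expected",
        [
            ("19:00", "01:00", 6.0),   # crosses midnight, read as 25:00
            ("19:00", "19:00", 0.0),
            ("19:00", "13:00", -6.0),  # symmetric advance
            ("23:00", "01:00", 2.0),
            ("01:00", "23:00", -2.0),
        ],
    )
    def test_unwrapping(self, off_a, off_b, expected):
        a = ld_phase(off=off_a)
        b = ld_phase(off=off_b, start=START + timedelta(days=1))
        assert dark_onset_shift(a, b) == pytest.approx(expected)

    def test_half_cycle_reported_as_delay(self):
        a, b = ld_phase(off="19:00"), ld_phase(off="07:00")
        assert dark_onset_shift(a, b) == 12.0

    def test_antisymmetric_mod_wrap(self):
        a, b = ld_phase(off="19:00"), ld_phase(off="01:00")
        assert dark_onset_shift(a, b) == -dark_onset_shift(b, a)

    def test_non_ld_phase_rejected(self):
        with pytest.raises(ScheduleError, match="undefined"):
            dark_onset_shift(dd_phase(), ld_phase())
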