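"""Stochastic virtual mouse: a circadian phase oscillator driving PIR-like
per-minute activity counts.

The animal is reduced to a single circadian phase variable theta in [0, 24)
circadian hours, with theta = 12 defined as activity onset (the CT12
convention for a nocturnal rodent: subjective night is 12 <= theta < 24).
The phase advances at its intrinsic rate 24/tau and is modulated by light
through a velocity phase-response curve:

    dtheta/dt = 24/tau + L(t) * (K/24) * PRC(theta),
    PRC(theta) = -sin(2*pi*(theta - 12)/24)

Light in the early subjective night delays the clock, light in the late
subjective night advances it, which is the qualitative shape measured in
rodents and yields stable (Type-1-like) entrainment. K is the maximal
velocity modulation, in hours of shift per 24 h of continuous light at peak
PRC. Over a half-sine lit window of w internal hours the largest achievable
shift per cycle is (K/24) * (tau/24) * (24/pi) * 2 * sin(pi*w/24), about
0.31*K h for a 12-h photoperiod, so the default K = 6.0 gives a range of
entrainment of roughly tau +/- 1.9 h - wide enough to lock onto T-cycles
from 23 to 25 h at the C57BL/6J preset tau = 23.7.

Activity is emitted as per-minute Poisson counts whose mean is gated by
circadian phase (rate_night during subjective night, rate_day otherwise) and
suppressed multiplicatively by light (masking), mimicking a PIR motion
sensor. Phase dynamics are deterministic given the light trace; randomness
enters only through the initial phase and the Poisson draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .schedule import LightTrace


@dataclass(frozen=True)
class MouseParams:
    """Virtual-animal parameters.

    tau : intrinsic free-running period, hours (C57BL/6J preset 23.7)
    prc_gain : K, maximal phase-velocity modulation, hours of shift per
        24 h of light exposure at peak PRC (default 6.0)
    masking : multiplicative activity suppression under light, in [0, 1]
        (default 0.05; 0 silences lit activity entirely)
    rate_night / rate_day : mean PIR counts per minute during subjective
        night / day (defaults 15.0 / 0.5)
    seed : random-stream seed (initial phase + Poisson draws)
    """

    tau: float = 23.7
    prc_gain: float = 6.0
    masking: float = 0.05
    rate_night: float = 15.0
    rate_day: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.masking <= 1.0:
            raise ValueError("masking must lie in [0, 1]")
        if self.rate_night < 0 or self.rate_day < 0:
            raise ValueError("rates must be non-negative")


#: C57BL/6J strain preset: mean free-running period 23.7 h; inter-individual
#: SD of about 10 min is modelled by simulate_population's tau_sd.
C57BL6J = MouseParams()

TAU_SD_C57BL6J = 10.0 / 60.0  # hours


@dataclass
class MouseState:
    """Evolving circadian phase (hours in [0, 24)) at an external time."""

    circadian_phase: float
    clock: float  # unix seconds


@dataclass(frozen=True)
class SimulationResult:
    """Per-minute counts and the underlying circadian phase series."""

    counts: np.ndarray
    phase: np.ndarray
    params: MouseParams
    trace: LightTrace

    def times_hours(self) -> np.ndarray:
        """Sample times in hours from the start of the trace."""
        return np.arange(len(self.counts)) / 60.0


def prc(theta: np.ndarray | float) -> np.ndarray | float:
    """Sinusoidal velocity phase-response curve, peak delay at theta = 18."""
    return -np.sin(2.0 * np.pi * (np.asarray(theta) - 12.0) / 24.0)


def simulate_activity(
    params: MouseParams,
    trace: LightTrace,
    initial_phase: Optional[float] = None,
    deterministic: bool = False,
) -> SimulationResult:
    """Integrate the phase oscillator along a light trace and draw counts.

    Parameters
    ----------
    params : MouseParams
    trace : LightTrace
        Must be sampled at 60-s steps (the logging resolution).
    initial_phase : float, optional
        Starting circadian phase in hours; drawn uniformly from [0, 24) if
        omitted.
    deterministic : bool
        Zero-noise mode: counts are the rounded expected rates instead of
        Poisson draws (for oracle tests).

    Identical params (seed included) and trace give identical output.
    """
    if trace.step != 60.0:
        raise ValueError(f"trace step must be 60 s, got {trace.step}")
    states = trace.states
    n = len(states)
    rng = np.random.default_rng(params.seed)
    theta0 = rng.uniform(0.0, 24.0) if initial_phase is None else float(initial_phase) % 24.0
    dt_h = 1.0 / 60.0
    omega = (24.0 / params.tau) * dt_h
    gain = (params.prc_gain / 24.0) * dt_h

    if states.any():
        phase = np.empty(n)
        theta = theta0
        two_pi_over_24 = 2.0 * math.pi / 24.0
        sin = math.sin
        for i in range(n):
            phase[i] = theta
            drive = omega
            if states[i]:
                drive -= gain * sin(two_pi_over_24 * (theta - 12.0))
            theta = (theta + drive) % 24.0
    else:
        # constant darkness: the oscillator is unforced and integrates in
        # closed form, which keeps population-scale simulations cheap
        phase = (theta0 + omega * np.arange(n)) % 24.0

    night = (phase >= 12.0) & (phase < 24.0)
    rates = np.where(night, params.rate_night, params.rate_day)
    rates = rates * np.where(states == 1, params.masking, 1.0)
    if deterministic:
        counts = np.rint(rates).astype(np.int64)
    else:
        counts = rng.poisson(rates)
    return SimulationResult(counts=counts, phase=phase, params=params, trace=trace)


def simulate_population(
    params: MouseParams, n: int, tau_sd: float = TAU_SD_C57BL6J
) -> list[MouseParams]:
    """Draw ``n`` animals with tau ~ Normal(params.tau, tau_sd).

    Per-animal seeds are params.seed + index, so the population is fully
    reproducible from the master seed, and n = 1 with tau_sd = 0 returns an
    exact clone of the input parameters.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if tau_sd < 0:
        raise ValueError("tau_sd must be non-negative")
    rng = np.random.default_rng(params.seed)
    taus = rng.normal(params.tau, tau_sd, size=n)
    taus = np.clip(taus, 1e-6, None)
    return [
        replace(params, tau=float(t), seed=params.seed + i)
        for i, t in enumerate(taus)
    ]
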