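"""Biphasic stimulation pulse scheduling and boost-converter voltage dynamics.

A stimulation cycle is one positive phase immediately followed by one negative
phase of equal width, then an inter-cycle pause; the pause absorbs the rest of
the period so that ``phase + phase + gap == period`` exactly.  Event times are
kept as integer microseconds internally so that timing assertions are exact and
free of float drift; the public API speaks seconds.

Polarity convention: the first phase of every cycle is positive (+1).  This is
arbitrary (an H-bridge is symmetric) and only needs to be consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

US_PER_S = 1_000_000

__all__ = [
    "StimulationParameters",
    "PulseSchedule",
    "WaveformStats",
    "BoostParams",
    "BoostState",
    "TimingViolationError",
    "InsufficientCyclesError",
    "UndersamplingError",
    "make_schedule",
    "schedule_stats",
    "boost_step",
    "boost_steady_state",
    "render_waveform",
    "schedule_to_csv",
    "schedule_from_csv",
]


class TimingViolationError(ValueError):
    """Raised when two phases cannot fit inside one period."""


class InsufficientCyclesError(ValueError):
    """Raised when a schedule has too few cycles to measure period/frequency."""


class UndersamplingError(ValueError):
    """Raised when the requested sample rate cannot resolve the phases."""


@dataclass(frozen=True)
class StimulationParameters:
    """Per-channel stimulus settings.

    Attributes
    ----------
    channel_id : int
        Stimulation channel index.
    frequency_hz : float
        Cycle repetition rate, > 0.
    pulse_duration_us : float
        Width of each phase in microseconds, > 0.  Two phases must fit in one
        period: ``2 * pulse_duration_us < 1e6 / frequency_hz``.
    amplitude_duty_pct : float
        Boost duty-cycle command in [0, 100] (stimulus amplitude).
    """

    channel_id: int
    frequency_hz: float
    pulse_duration_us: float
    amplitude_duty_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError(f"frequency_hz must be > 0, got {self.frequency_hz}")
        if self.pulse_duration_us <= 0:
            raise ValueError(
                f"pulse_duration_us must be > 0, got {self.pulse_duration_us}"
            )
        if not 0.0 <= self.amplitude_duty_pct <= 100.0:
            raise ValueError(
                f"amplitude_duty_pct must be in [0, 100], got {self.amplitude_duty_pct}"
            )
        if 2.0 * self.pulse_duration_us >= US_PER_S / self.frequency_hz:
            raise TimingViolationError(
                "two phases of "
                f"{self.pulse_duration_us} us do not fit in a "
                f"{US_PER_S / self.frequency_hz:.1f} us period"
            )

    @property
    def period_us(self) -> int:
        """Cycle period rounded to the nearest microsecond."""
        return round(US_PER_S / self.frequency_hz)


@dataclass(frozen=True)
class PulseSchedule:
    """Time-sorted biphasic pulse events for one channel.

    ``starts_us``/``ends_us``/``polarities`` are parallel arrays; polarity is
    +1 or -1 and events never overlap.  Times are integer microseconds.
    """

    channel_id: int
    starts_us: np.ndarray
    ends_us: np.ndarray
    polarities: np.ndarray
    total_duration_s: float

    def __post_init__(self) -> None:
        n = len(self.starts_us)
        if not (len(self.ends_us) == len(self.polarities) == n):
            raise ValueError("event arrays must have equal length")
        if n:
            if np.any(self.ends_us <= self.starts_us):
                raise ValueError("every event must have end > start")
            if np.any(self.starts_us[1:] < self.ends_us[:-1]):
                raise ValueError("events must be non-overlapping and sorted")

    @property
    def n_events(self) -> int:
        return len(self.starts_us)

    @property
    def n_cycles(self) -> int:
        return int(np.sum(self.polarities == 1))

    @property
    def events(self) -> list[tuple[float, float, int]]:
        """Events as (start_s, end_s, polarity) tuples."""
        return [
            (s / US_PER_S, e / US_PER_S, int(p))
            for s, e, p in zip(self.starts_us, self.ends_us, self.polarities)
        ]


@dataclass(frozen=True)
class WaveformStats:
    """Timing measured from a schedule, not echoed from its parameters."""

    frequency_hz: float
    period_ms: float
    phase_width_us: float
    n_cycles: int
    n_irregular: int = 0  # cycles whose spacing or phase width deviates


def make_schedule(params: StimulationParameters, duration_s: float) -> PulseSchedule:
    """Lay out biphasic cycles over ``duration_s`` seconds.

    Each cycle k occupies ``[k*T, k*T + 2*phase]`` with the +1 phase first;
    cycles whose phases would be cut by the duration boundary are dropped
    entirely so every emitted cycle is complete.
    """
    if duration_s < 0:
        raise ValueError(f"duration_s must be >= 0, got {duration_s}")
    period_us = params.period_us
    phase_us = round(params.pulse_duration_us)
    if 2 * phase_us >= period_us:
        raise TimingViolationError(
            f"2 x {phase_us} us phases do not fit in {period_us} us period"
        )
    duration_us = math.floor(duration_s * US_PER_S)
    if duration_us < 2 * phase_us:
        n_cycles = 0
    else:
        # cycle k fits iff k*T + 2*phase <= duration
        n_cycles = (duration_us - 2 * phase_us) // period_us + 1
    k = np.arange(n_cycles, dtype=np.int64)
    cycle_starts = k * period_us
    starts = np.empty(2 * n_cycles, dtype=np.int64)
    ends = np.empty(2 * n_cycles, dtype=np.int64)
    pols = np.empty(2 * n_cycles, dtype=np.int8)
    starts[0::2] = cycle_starts
    ends[0::2] = cycle_starts + phase_us
    pols[0::2] = 1
    starts[1::2] = cycle_starts + phase_us
    ends[1::2] = cycle_starts + 2 * phase_us
    pols[1::2] = -1
    return PulseSchedule(
        channel_id=params.channel_id,
        starts_us=starts,
        ends_us=ends,
        polarities=pols,
        total_duration_s=float(duration_s),
    )


def schedule_stats(schedule: PulseSchedule) -> WaveformStats:
    """Measure period, frequency and phase width from cycle spacings.

    Requires at least two cycles (one spacing).  ``n_irregular`` counts cycles
    whose start-to-start spacing or phase width deviates from the modal value.
    """
    pos = schedule.polarities == 1
    cycle_starts = schedule.starts_us[pos]
    if len(cycle_starts) < 2:
        raise InsufficientCyclesError(
            f"need >= 2 cycles to measure a period, got {len(cycle_starts)}"
        )
    spacings = np.diff(cycle_starts)
    widths = schedule.ends_us - schedule.starts_us
    period_us = float(np.median(spacings))
    phase_us = float(np.median(widths))
    irregular = int(np.sum(spacings != spacings[0]))
    irregular += int(np.sum(widths != widths[0]))
    return WaveformStats(
        frequency_hz=US_PER_S / period_us,
        period_ms=period_us / 1000.0,
        phase_width_us=phase_us,
        n_cycles=len(cycle_starts),
        n_irregular=irregular,
    )


# --------------------------------------------------------------------------
# Boost converter


@dataclass(frozen=True)
class BoostParams:
    """Idealised boost stage: 7 V rail, 100 V ceiling, asymmetric lag.

    The converter output relaxes toward the continuous-conduction target
    ``V_in / (1 - duty/100)`` (clamped at ``v_max``) with a shorter time
    constant when charging than when discharging — the capacitor charges
    faster than it discharges.
    """

    v_in: float = 7.0
    v_max: float = 100.0
    tau_up_s: float = 0.010
    tau_down_s: float = 0.050

    def __post_init__(self) -> None:
        if not 0 < self.v_in <= self.v_max:
            raise ValueError("need 0 < v_in <= v_max")
        if not 0 < self.tau_up_s < self.tau_down_s:
            raise ValueError("need 0 < tau_up_s < tau_down_s (charge faster than discharge)")


@dataclass(frozen=True)
class BoostState:
    voltage_v: float
    duty_pct: float = 0.0


def boost_target(duty_pct: float, params: BoostParams = BoostParams()) -> float:
    """Steady-state output voltage for a given duty command."""
    if duty_pct >= 100.0:
        return params.v_max
    return min(params.v_in / (1.0 - duty_pct / 100.0), params.v_max)


def boost_step(
    state: BoostState,
    duty_pct: float,
    dt: float,
    params: BoostParams = BoostParams(),
) -> BoostState:
    """Advance the boost output by ``dt`` seconds toward its duty target.

    Out-of-range duty is clamped with a warning rather than rejected; the
    hardware PWM peripheral would do the same.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if not 0.0 <= duty_pct <= 100.0:
        warnings.warn(
            f"duty {duty_pct}% outside [0, 100], clamping", stacklevel=2
        )
        duty_pct = min(max(duty_pct, 0.0), 100.0)
    target = boost_target(duty_pct, params)
    tau = params.tau_up_s if target > state.voltage_v else params.tau_down_s
    v = state.voltage_v + (target - state.voltage_v) * (1.0 - math.exp(-dt / tau))
    v = min(max(v, 0.0), params.v_max)
    return BoostState(voltage_v=v, duty_pct=duty_pct)


def boost_steady_state(
    state: BoostState,
    duty_pct: float,
    params: BoostParams = BoostParams(),
    dt: float = 1e-3,
    tol: float = 1e-9,
    max_steps: int = 2_000_000,
) -> BoostState:
    """Iterate ``boost_step`` until the voltage stops moving."""
    for _ in range(max_steps):
        nxt = boost_step(state, duty_pct, dt, params)
        if abs(nxt.voltage_v - state.voltage_v) < tol:
            return nxt
        state = nxt
    return state


# --------------------------------------------------------------------------
# Rendering and CSV round trip


def render_waveform(
    schedule: PulseSchedule, voltage_v: float, sample_rate_hz: float
) -> np.ndarray:
    """Sample the schedule as a voltage trace.

    The trace is ``+V`` during positive phases, ``-V`` during negative phases
    and 0 in the gaps; sample ``i`` covers ``[i/fs, (i+1)/fs)``.  Rejects
    sample rates below two samples per phase (10 kHz for 200 us phases).
    """
    if voltage_v < 0:
        raise ValueError("voltage_v must be >= 0")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be > 0")
    n_samples = math.ceil(schedule.total_duration_s * sample_rate_hz)
    trace = np.zeros(n_samples)
    if schedule.n_events == 0:
        return trace
    phase_us = int(np.min(schedule.ends_us - schedule.starts_us))
    if sample_rate_hz < 2.0 * US_PER_S / phase_us:
        raise UndersamplingError(
            f"sample rate {sample_rate_hz} Hz below 2 samples per {phase_us} us phase"
        )
    for start, end, pol in zip(
        schedule.starts_us, schedule.ends_us, schedule.polarities
    ):
        i0 = math.ceil(start * sample_rate_hz / US_PER_S - 1e-9)
        i1 = math.ceil(end * sample_rate_hz / US_PER_S - 1e-9)
        trace[i0:min(i1, n_samples)] = pol * voltage_v
    return trace


def schedule_to_csv(schedule: PulseSchedule, path) -> None:
    """Write events as CSV: channel, start_s, end_s, polarity."""
    pd.DataFrame(
        {
            "channel": schedule.channel_id,
            "start_s": schedule.starts_us / US_PER_S,
            "end_s": schedule.ends_us / US_PER_S,
            "polarity": schedule.polarities.astype(int),
        }
    ).to_csv(path, index=False)


def schedule_from_csv(path) -> PulseSchedule:
    df = pd.read_csv(path)
    required = {"channel", "start_s", "end_s", "polarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule CSV missing columns: {sorted(missing)}")
    channels = df["channel"].unique()
    if len(channels) > 1:
        raise ValueError("schedule CSV must contain a single channel")
    starts = np.round(df["start_s"].to_numpy() * US_PER_S).astype(np.int64)
    ends = np.round(df["end_s"].to_numpy() * US_PER_S).astype(np.int64)
    pols = df["polarity"].to_numpy().astype(np.int8)
    total = ends[-1] / US_PER_S if len(ends) else 0.0
    return PulseSchedule(
        channel_id=int(channels[0]) if len(channels) else 0,
        starts_us=starts,
        ends_us=ends,
        polarities=pols,
        total_duration_s=float(total),
    )
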