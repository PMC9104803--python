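"""Closed-loop session orchestration.

Per control tick the loop is: read IMU -> complementary filter -> error per
degree of freedom -> one PID per degree of freedom -> muscle selector ->
plant.  The controllers see the *filtered* angle estimate, as the real device
does; the true plant angle is logged for evaluation only.

The shipped protocol mirrors the proof-of-concept sequence: neutral hold,
inversion (+20 deg frontal), eversion (-5 deg frontal, a shorter hold),
neutral, dorsiflexion (+20 deg sagittal), plantar flexion (-20 deg sagittal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import orientation, pid, plant as plant_mod, selector
from .orientation import FilterState, JointAngles, accel_inclination
from .pid import PIDGains, PIDState, pid_step
from .plant import AnklePlantParams, initial_state, plant_step, synth_imu
from .selector import ChannelPair, default_pairs, route_action
from .waveform import StimulationParameters

__all__ = [
    "SetpointSegment",
    "SetpointProfile",
    "SessionConfig",
    "SessionLog",
    "StepMetrics",
    "SafetyStopError",
    "protocol_setpoints",
    "default_config",
    "run_session",
    "step_response",
    "tracking_metrics",
]


class SafetyStopError(RuntimeError):
    """Raised when a commanded duty exceeds the configured safety ceiling."""


@dataclass(frozen=True)
class SetpointSegment:
    start_s: float
    end_s: float
    sagittal_ref_deg: float
    frontal_ref_deg: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"segment {self.label!r}: end must be after start")


@dataclass(frozen=True)
class SetpointProfile:
    """Contiguous, non-overlapping reference segments starting at neutral."""

    segments: tuple[SetpointSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile needs at least one segment")
        first = self.segments[0]
        if first.start_s != 0.0:
            raise ValueError("profile must start at t = 0")
        if first.sagittal_ref_deg != 0.0 or first.frontal_ref_deg != 0.0:
            raise ValueError("profile must start at the neutral reference (0, 0)")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_s != a.end_s:
                raise ValueError(
                    f"segments {a.label!r} and {b.label!r} are not contiguous"
                )

    @property
    def duration_s(self) -> float:
        return self.segments[-1].end_s

    def refs_at(self, t: float) -> tuple[float, float]:
        """(sagittal_ref, frontal_ref) at time t; clamps past the last segment."""
        for seg in self.segments:
            if seg.start_s <= t < seg.end_s:
                return seg.sagittal_ref_deg, seg.frontal_ref_deg
        last = self.segments[-1]
        return last.sagittal_ref_deg, last.frontal_ref_deg


def protocol_setpoints(
    hold_s: float = 10.0, eversion_hold_s: float = 5.0
) -> SetpointProfile:
    """Sequential ankle protocol: inversion, eversion (shorter), dorsiflexion,
    plantar flexion, with neutral holds at the start and between planes."""
    segs = []
    t = 0.0

    def add(duration: float, sag: float, fro: float, label: str) -> None:
        nonlocal t
        segs.append(SetpointSegment(t, t + duration, sag, fro, label))
        t += duration

    add(hold_s, 0.0, 0.0, "neutral")
    add(hold_s, 0.0, 20.0, "inversion")
    add(eversion_hold_s, 0.0, -5.0, "eversion")
    add(hold_s, 0.0, 0.0, "neutral_2")
    add(hold_s, 20.0, 0.0, "dorsiflexion")
    add(hold_s, -20.0, 0.0, "plantar_flexion")
    return SetpointProfile(tuple(segs))


# --------------------------------------------------------------------------
# Configuration


def _table_gains_sagittal() -> PIDGains:
    return PIDGains(kp=8.2, ki=3.8, kd=0.0, u_min=-14.0, u_max=10.0)


def _table_gains_frontal() -> PIDGains:
    return PIDGains(kp=8.1, ki=3.2, kd=0.0, u_min=-12.0, u_max=14.0)


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to reproduce a closed-loop run."""

    imu_rate_hz: float = 100.0
    duration_s: float | None = None  # None -> profile duration
    stimulation: tuple[StimulationParameters, ...] = ()
    pid_sagittal: PIDGains = field(default_factory=_table_gains_sagittal)
    pid_frontal: PIDGains = field(default_factory=_table_gains_frontal)
    filter_alpha: float = 0.98
    pairs: dict[str, ChannelPair] = field(default_factory=default_pairs)
    profile: SetpointProfile = field(default_factory=protocol_setpoints)
    seed: int = 0
    duty_ceiling_pct: float = 100.0

    def validate(self) -> list[str]:
        problems = []
        if self.imu_rate_hz <= 0:
            problems.append(f"imu_rate_hz must be > 0, got {self.imu_rate_hz}")
        if self.duration_s is not None and self.duration_s <= 0:
            problems.append(f"duration_s must be > 0, got {self.duration_s}")
        if not 0.0 <= self.filter_alpha <= 1.0:
            problems.append(f"filter_alpha must be in [0, 1], got {self.filter_alpha}")
        if not 0.0 < self.duty_ceiling_pct <= 100.0:
            problems.append(
                f"duty_ceiling_pct must be in (0, 100], got {self.duty_ceiling_pct}"
            )
        for dof in ("sagittal", "frontal"):
            if dof not in self.pairs:
                problems.append(f"missing channel pair for dof {dof!r}")
        seen: dict[int, str] = {}
        for dof, pair in self.pairs.items():
            for ch in pair.channels:
                if ch in seen:
                    problems.append(
                        f"channel {ch} assigned to both {seen[ch]!r} and {dof!r}"
                    )
                seen[ch] = dof
        ids = [p.channel_id for p in self.stimulation]
        if len(ids) != len(set(ids)):
            problems.append("duplicate channel_id in stimulation parameters")
        return problems

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("invalid session config:\n  " + "\n  ".join(problems))

    @property
    def control_dt_s(self) -> float:
        return 1.0 / self.imu_rate_hz

    @property
    def effective_duration_s(self) -> float:
        return self.duration_s if self.duration_s is not None else self.profile.duration_s


def default_config(seed: int = 0) -> SessionConfig:
    """Reference configuration: 100 Hz loop, the published PI gains and the
    50 Hz / 200 us / 5 % baseline stimulation settings on all four channels."""
    stim = tuple(
        StimulationParameters(
            channel_id=ch, frequency_hz=50.0, pulse_duration_us=200.0,
            amplitude_duty_pct=5.0,
        )
        for ch in range(4)
    )
    return SessionConfig(stimulation=stim, seed=seed)


# --------------------------------------------------------------------------
# Session log


@dataclass
class SessionLog:
    """Time-indexed record of one closed-loop run.

    All arrays share one row per control tick.  ``header`` carries the full
    configuration (as a plain dict) and the seed.
    """

    header: dict
    profile: SetpointProfile
    channel_ids: tuple[int, ...]
    t_s: np.ndarray
    ref_sagittal_deg: np.ndarray
    ref_frontal_deg: np.ndarray
    est_sagittal_deg: np.ndarray
    est_frontal_deg: np.ndarray
    true_sagittal_deg: np.ndarray
    true_frontal_deg: np.ndarray
    u_sagittal: np.ndarray
    u_frontal: np.ndarray
    sat_sagittal: np.ndarray
    sat_frontal: np.ndarray
    duties_pct: np.ndarray  # shape (n_ticks, n_channels)

    def __len__(self) -> int:
        return len(self.t_s)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "t_s": self.t_s,
            "ref_sagittal_deg": self.ref_sagittal_deg,
            "ref_frontal_deg": self.ref_frontal_deg,
            "est_sagittal_deg": self.est_sagittal_deg,
            "est_frontal_deg": self.est_frontal_deg,
            "true_sagittal_deg": self.true_sagittal_deg,
            "true_frontal_deg": self.true_frontal_deg,
            "u_sagittal": self.u_sagittal,
            "u_frontal": self.u_frontal,
            "sat_sagittal": self.sat_sagittal,
            "sat_frontal": self.sat_frontal,
        }
        for j, ch in enumerate(self.channel_ids):
            data[f"duty_ch{ch}_pct"] = self.duties_pct[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        """CSV export with the header embedded as a leading JSON comment."""
        import json

        with open(path, "w") as fh:
            fh.write("# fesloop-session-header: " + json.dumps(self.header) + "\n")
            self.to_dataframe().to_csv(fh, index=False)


# --------------------------------------------------------------------------
# The loop


def run_session(
    config: SessionConfig,
    plant_params: AnklePlantParams,
    header_extra: dict | None = None,
) -> SessionLog:
    """Simulate one closed-loop session; deterministic given ``config.seed``.

    Raises :class:`SafetyStopError` if any commanded duty exceeds
    ``config.duty_ceiling_pct`` (the software analogue of the pain-threshold
    stop rule).
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid session config:\n  " + "\n  ".join(problems))
    for dof, pair in config.pairs.items():
        for ch in pair.channels:
            if ch not in plant_params.channels:
                raise ValueError(f"pair {dof!r} references unknown plant channel {ch}")

    rng = np.random.default_rng(config.seed)
    dt = config.control_dt_s
    n_ticks = int(round(config.effective_duration_s * config.imu_rate_hz))
    channel_ids = tuple(sorted(
        set(config.pairs["sagittal"].channels) | set(config.pairs["frontal"].channels)
    ))

    state = initial_state(plant_params)
    pid_states = {"sagittal": PIDState(), "frontal": PIDState()}
    gains = {"sagittal": config.pid_sagittal, "frontal": config.pid_frontal}
    filt: FilterState | None = None

    cols = {
        name: np.empty(n_ticks)
        for name in (
            "t", "ref_sag", "ref_fro", "est_sag", "est_fro",
            "true_sag", "true_fro", "u_sag", "u_fro",
        )
    }
    sat_sag = np.empty(n_ticks, dtype=bool)
    sat_fro = np.empty(n_ticks, dtype=bool)
    duties = np.empty((n_ticks, len(channel_ids)))

    for k in range(n_ticks):
        t = k * dt
        sample = synth_imu(state, plant_params, rng, timestamp_s=t)
        if filt is None:
            filt = FilterState(
                angles=accel_inclination(sample),
                alpha=config.filter_alpha,
                last_timestamp_s=t,
            )
        else:
            filt = orientation.comp_filter_update(filt, sample)

        ref_sag, ref_fro = config.profile.refs_at(t)
        est = filt.angles
        actions = {}
        for dof, ref, est_deg in (
            ("sagittal", ref_sag, est.sagittal_deg),
            ("frontal", ref_fro, est.frontal_deg),
        ):
            action, pid_states[dof] = pid_step(
                gains[dof], pid_states[dof], ref - est_deg, dt
            )
            actions[dof] = action

        command = route_action(actions["sagittal"], config.pairs["sagittal"]).merged(
            route_action(actions["frontal"], config.pairs["frontal"])
        )
        worst = max(command.duties.values(), default=0.0)
        if worst > config.duty_ceiling_pct:
            raise SafetyStopError(
                f"duty {worst:.2f}% exceeds safety ceiling "
                f"{config.duty_ceiling_pct}% at t = {t:.3f} s"
            )

        cols["t"][k] = t
        cols["ref_sag"][k] = ref_sag
        cols["ref_fro"][k] = ref_fro
        cols["est_sag"][k] = est.sagittal_deg
        cols["est_fro"][k] = est.frontal_deg
        cols["true_sag"][k] = state.angles_deg["sagittal"]
        cols["true_fro"][k] = state.angles_deg["frontal"]
        cols["u_sag"][k] = actions["sagittal"].u
        cols["u_fro"][k] = actions["frontal"].u
        sat_sag[k] = actions["sagittal"].saturated
        sat_fro[k] = actions["frontal"].saturated
        duties[k] = [command.duty(ch) for ch in channel_ids]

        state = plant_step(plant_params, state, command, dt, rng)

    header = {
        "seed": config.seed,
        "imu_rate_hz": config.imu_rate_hz,
        "duration_s": config.effective_duration_s,
        "filter_alpha": config.filter_alpha,
        "duty_ceiling_pct": config.duty_ceiling_pct,
        "pid_sagittal": vars(config.pid_sagittal).copy(),
        "pid_frontal": vars(config.pid_frontal).copy(),
        "channel_ids": list(channel_ids),
    }
    if header_extra:
        header.update(header_extra)
    return SessionLog(
        header=header,
        profile=config.profile,
        channel_ids=channel_ids,
        t_s=cols["t"],
        ref_sagittal_deg=cols["ref_sag"],
        ref_frontal_deg=cols["ref_fro"],
        est_sagittal_deg=cols["est_sag"],
        est_frontal_deg=cols["est_fro"],
        true_sagittal_deg=cols["true_sag"],
        true_frontal_deg=cols["true_fro"],
        u_sagittal=cols["u_sag"],
        u_frontal=cols["u_fro"],
        sat_sagittal=sat_sag,
        sat_frontal=sat_fro,
        duties_pct=duties,
    )


# --------------------------------------------------------------------------
# Step response and tracking metrics


@dataclass(frozen=True)
class StepMetrics:
    rise_time_s: float  # 10% -> 90% of the step
    overshoot_deg: float  # beyond the target, >= 0
    steady_state_error_deg: float  # signed: target - mean of the final second
    settling_time_s: float  # time to stay within the band around the target


def step_response(
    config: SessionConfig,
    plant_params: AnklePlantParams,
    dof: str,
    step_deg: float,
    neutral_s: float = 2.0,
    hold_s: float = 8.0,
) -> StepMetrics:
    """Apply one setpoint step from neutral and measure the true response."""
    if dof not in ("sagittal", "frontal"):
        raise ValueError(f"unknown dof {dof!r}")
    dp = plant_params.dofs[dof]
    if not dp.angle_min_deg <= step_deg <= dp.angle_max_deg:
        raise ValueError(
            f"step {step_deg} deg outside plant limits "
            f"[{dp.angle_min_deg}, {dp.angle_max_deg}]"
        )
    if step_deg == 0.0:
        return StepMetrics(0.0, 0.0, 0.0, 0.0)

    sag = step_deg if dof == "sagittal" else 0.0
    fro = step_deg if dof == "frontal" else 0.0
    profile = SetpointProfile(
        (
            SetpointSegment(0.0, neutral_s, 0.0, 0.0, "neutral"),
            SetpointSegment(neutral_s, neutral_s + hold_s, sag, fro, "step"),
        )
    )
    cfg = replace(config, profile=profile, duration_s=None)
    log = run_session(cfg, plant_params)

    angle = log.true_sagittal_deg if dof == "sagittal" else log.true_frontal_deg
    t = log.t_s
    after = t >= neutral_s
    y = angle[after] - angle[after][0]
    ts = t[after] - neutral_s
    sign = math.copysign(1.0, step_deg)
    yn = sign * y / abs(step_deg)  # normalised response, target 1.0

    def first_crossing(level: float) -> float:
        idx = np.argmax(yn >= level)
        if yn[idx] < level:
            return math.nan
        return float(ts[idx])

    t10, t90 = first_crossing(0.1), first_crossing(0.9)
    rise = t90 - t10 if not (math.isnan(t10) or math.isnan(t90)) else math.nan
    overshoot = max(float(np.max(yn)) - 1.0, 0.0) * abs(step_deg)
    final_second = ts >= ts[-1] - 1.0
    sse = step_deg - sign * float(np.mean(yn[final_second])) * abs(step_deg)
    band = max(0.02, 0.25 / abs(step_deg))  # normalised: 2% or 0.25 deg
    outside = np.abs(yn - 1.0) > band
    if not outside.any():
        settling = 0.0
    elif outside[-1]:
        settling = math.nan  # never settled within the simulated hold
    else:
        settling = float(ts[int(np.max(np.nonzero(outside)[0])) + 1])
    return StepMetrics(
        rise_time_s=rise,
        overshoot_deg=overshoot,
        steady_state_error_deg=sse,
        settling_time_s=settling,
    )


def tracking_metrics(log: SessionLog, settle_s: float = 2.0) -> list[dict]:
    """Per-segment summary: peak achieved angle, mean |error| after a settling
    window, and the fraction of ticks with a saturated controller."""
    if len(log) == 0:
        raise ValueError("empty session log")
    out = []
    for seg in log.profile.segments:
        mask = (log.t_s >= seg.start_s) & (log.t_s < seg.end_s)
        if not mask.any():
            continue
        settled = mask & (log.t_s >= seg.start_s + settle_s)
        if not settled.any():
            settled = mask
        if seg.sagittal_ref_deg != 0.0:
            dof, ref = "sagittal", seg.sagittal_ref_deg
            angle = log.true_sagittal_deg
        elif seg.frontal_ref_deg != 0.0:
            dof, ref = "frontal", seg.frontal_ref_deg
            angle = log.true_frontal_deg
        else:
            dof, ref, angle = None, 0.0, None
        if dof is None:
            dev = np.maximum(
                np.abs(log.true_sagittal_deg[mask]), np.abs(log.true_frontal_deg[mask])
            )
            peak = float(np.max(dev))
            err = float(
                np.mean(
                    np.abs(log.ref_sagittal_deg[settled] - log.true_sagittal_deg[settled])
                    + np.abs(log.ref_frontal_deg[settled] - log.true_frontal_deg[settled])
                )
            )
        else:
            sign = math.copysign(1.0, ref)
            peak = sign * float(np.max(sign * angle[mask]))
            err = float(np.mean(np.abs(ref - angle[settled])))
        frac_sat = float(np.mean(log.sat_sagittal[mask] | log.sat_frontal[mask]))
        out.append(
            {
                "label": seg.label,
                "dof": dof,
                "start_s": seg.start_s,
                "end_s": seg.end_s,
                "reference_deg": ref,
                "peak_deg": peak,
                "mean_abs_error_deg": err,
                "frac_saturated": frac_sat,
            }
        )
    return out
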