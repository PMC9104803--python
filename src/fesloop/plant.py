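"""Synthetic ankle + strapped-IMU plant for desk-scale closed-loop runs.

Two uncoupled rotational degrees of freedom (sagittal, frontal), each a
linear second-order joint (inertia-damper-spring returning to a rest angle)
driven by up to two stimulation channels through a static recruitment map —
zero below a motor-threshold duty, full activation at a saturation duty,
linear in between — followed by a first-order activation lag.  Disturbance
torques and IMU noise are optional, zero-mean Gaussian, drawn from a caller
supplied generator; with all sigmas zero the plant draws nothing, so runs are
bit-reproducible regardless of generator state.

Mechanical units are per-degree (stiffness in N*m/deg, damping in
N*m/(deg/s), inertia in N*m/(deg/s^2)) so that the static balance
``angle = rest + torque / stiffness`` reads directly in degrees.

Hard stops clip the angle at configured limits and zero the velocity, the
simplest model of the articular end range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .orientation import IMUSample
from .selector import ChannelCommand

__all__ = [
    "DofParams",
    "ChannelActuator",
    "NoiseParams",
    "AnklePlantParams",
    "AnklePlantState",
    "recruitment",
    "plant_step",
    "synth_imu",
    "default_plant",
    "initial_state",
]

MAX_STABLE_DT_S = 0.01
INTERNAL_DT_S = 0.001


@dataclass(frozen=True)
class DofParams:
    """Second-order joint parameters for one degree of freedom."""

    inertia_j: float  # N*m per (deg/s^2)
    damping_b: float  # N*m per (deg/s)
    stiffness_k: float  # N*m per deg (passive return to rest)
    rest_angle_deg: float
    angle_min_deg: float
    angle_max_deg: float

    def __post_init__(self) -> None:
        if min(self.inertia_j, self.damping_b, self.stiffness_k) <= 0:
            raise ValueError("inertia, damping and stiffness must be > 0")
        if not self.angle_min_deg < self.rest_angle_deg < self.angle_max_deg:
            raise ValueError("angle limits must bracket the rest angle")


@dataclass(frozen=True)
class ChannelActuator:
    """Duty -> torque path of one stimulation channel.

    ``direction`` is +1 for the agonist (increases the angle) and -1 for the
    antagonist of its degree of freedom.
    """

    dof: str
    direction: int
    max_torque_nm: float
    duty_threshold_pct: float  # motor threshold (deadzone)
    duty_saturation_pct: float  # full recruitment
    activation_tau_s: float

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if not 0.0 <= self.duty_threshold_pct < self.duty_saturation_pct <= 100.0:
            raise ValueError("need 0 <= threshold < saturation <= 100")
        if self.max_torque_nm <= 0 or self.activation_tau_s <= 0:
            raise ValueError("max_torque_nm and activation_tau_s must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    accel_sigma_g: float = 0.0
    gyro_sigma_dps: float = 0.0
    disturbance_sigma_nm: float = 0.0
    disturbance_drift_sigma_nm: float = 0.0  # random-walk step std per sqrt(s)

    def __post_init__(self) -> None:
        for name in (
            "accel_sigma_g",
            "gyro_sigma_dps",
            "disturbance_sigma_nm",
            "disturbance_drift_sigma_nm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AnklePlantParams:
    dofs: dict[str, DofParams]
    channels: dict[int, ChannelActuator]
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        for ch, act in self.channels.items():
            if act.dof not in self.dofs:
                raise ValueError(f"channel {ch} references unknown dof {act.dof!r}")


@dataclass(frozen=True)
class AnklePlantState:
    angles_deg: dict[str, float]
    velocities_dps: dict[str, float]
    activations: dict[int, float]
    drift_torques_nm: dict[str, float] = field(default_factory=dict)


def initial_state(params: AnklePlantParams) -> AnklePlantState:
    """Plant at rest: angles at the rest pose, zero velocity and activation."""
    return AnklePlantState(
        angles_deg={d: p.rest_angle_deg for d, p in params.dofs.items()},
        velocities_dps={d: 0.0 for d in params.dofs},
        activations={ch: 0.0 for ch in params.channels},
        drift_torques_nm={d: 0.0 for d in params.dofs},
    )


def recruitment(duty_pct: float, actuator: ChannelActuator) -> float:
    """Static duty -> activation-target map: deadzone, linear ramp, saturation."""
    if not 0.0 <= duty_pct <= 100.0:
        raise ValueError(f"duty must be in [0, 100], got {duty_pct}")
    lo, hi = actuator.duty_threshold_pct, actuator.duty_saturation_pct
    if duty_pct <= lo:
        return 0.0
    if duty_pct >= hi:
        return 1.0
    return (duty_pct - lo) / (hi - lo)


def plant_step(
    params: AnklePlantParams,
    state: AnklePlantState,
    command: ChannelCommand,
    dt: float,
    rng: np.random.Generator | None = None,
) -> AnklePlantState:
    """Advance the plant by ``dt`` seconds under a channel duty command.

    Integrates with semi-implicit Euler at internal 1 ms substeps (``dt`` up
    to 10 ms is accepted and subdivided).  Activation relaxes exponentially
    toward its recruitment target; net joint torque is muscle + spring +
    damper + disturbance.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt > MAX_STABLE_DT_S + 1e-12:
        raise ValueError(f"dt {dt} s exceeds the stable limit {MAX_STABLE_DT_S} s")
    noise = params.noise
    stochastic = noise.disturbance_sigma_nm > 0 or noise.disturbance_drift_sigma_nm > 0
    if stochastic and rng is None:
        raise ValueError("an rng is required when disturbance sigmas are nonzero")

    n_sub = max(1, math.ceil(dt / INTERNAL_DT_S - 1e-12))
    h = dt / n_sub

    activations = dict(state.activations)
    angles = dict(state.angles_deg)
    velocities = dict(state.velocities_dps)
    drifts = dict(state.drift_torques_nm) or {d: 0.0 for d in params.dofs}

    targets = {
        ch: recruitment(command.duty(ch), act) for ch, act in params.channels.items()
    }

    for _ in range(n_sub):
        for ch, act in params.channels.items():
            decay = 1.0 - math.exp(-h / act.activation_tau_s)
            activations[ch] += (targets[ch] - activations[ch]) * decay
        for dof, dp in params.dofs.items():
            torque = dp.stiffness_k * (dp.rest_angle_deg - angles[dof])
            torque -= dp.damping_b * velocities[dof]
            for ch, act in params.channels.items():
                if act.dof == dof:
                    torque += act.direction * activations[ch] * act.max_torque_nm
            if stochastic:
                if noise.disturbance_drift_sigma_nm > 0:
                    drifts[dof] += rng.normal(
                        0.0, noise.disturbance_drift_sigma_nm * math.sqrt(h)
                    )
                torque += drifts[dof]
                if noise.disturbance_sigma_nm > 0:
                    torque += rng.normal(0.0, noise.disturbance_sigma_nm)
            velocities[dof] += h * torque / dp.inertia_j
            angles[dof] += h * velocities[dof]
            if angles[dof] <= dp.angle_min_deg:
                angles[dof] = dp.angle_min_deg
                velocities[dof] = 0.0
            elif angles[dof] >= dp.angle_max_deg:
                angles[dof] = dp.angle_max_deg
                velocities[dof] = 0.0

    return AnklePlantState(
        angles_deg=angles,
        velocities_dps=velocities,
        activations=activations,
        drift_torques_nm=drifts,
    )


def synth_imu(
    state: AnklePlantState,
    params: AnklePlantParams,
    rng: np.random.Generator | None = None,
    timestamp_s: float = 0.0,
) -> IMUSample:
    """Emit one IMU reading for the current pose.

    The accelerometer vector points along gravity for the current tilt, up to
    a scale factor: the components are (tan(sagittal), tan(frontal), 1), so
    ``accel_inclination`` (which is scale-invariant) recovers each true angle
    exactly and, crucially, each axis independently of the other — the
    normalisation that would couple them numerically is omitted on purpose.
    Gyro x/y carry the true angular velocities.  Gaussian noise per sigma.
    """
    noise = params.noise
    noisy = noise.accel_sigma_g > 0 or noise.gyro_sigma_dps > 0
    if noisy and rng is None:
        raise ValueError("an rng is required when IMU noise sigmas are nonzero")

    sag = math.radians(state.angles_deg.get("sagittal", 0.0))
    fro = math.radians(state.angles_deg.get("frontal", 0.0))
    accel = np.array([math.tan(sag), math.tan(fro), 1.0])
    gyro = np.array(
        [
            state.velocities_dps.get("sagittal", 0.0),
            state.velocities_dps.get("frontal", 0.0),
            0.0,
        ]
    )
    if noisy:
        if noise.accel_sigma_g > 0:
            accel = accel + rng.normal(0.0, noise.accel_sigma_g, size=3)
        if noise.gyro_sigma_dps > 0:
            gyro = gyro + rng.normal(0.0, noise.gyro_sigma_dps, size=3)
    return IMUSample(
        timestamp_s=timestamp_s,
        accel_g=(float(accel[0]), float(accel[1]), float(accel[2])),
        gyro_dps=(float(gyro[0]), float(gyro[1]), float(gyro[2])),
    )


def default_plant() -> AnklePlantParams:
    """Reference noise-free plant used by documentation, fixtures and tests.

    Sizing rationale (kept here so the numbers are auditable):

    * stiffness 0.5 N*m/deg with 20 N*m channel torque gives a 40 deg span at
      full recruitment, enough margin for 20 deg targets;
    * recruitment thresholds 3 % / 14 % mean the controller limit magnitudes
      (10-14 duty %) span most of the recruitment range while small regulatory
      duties fall in the deadzone;
    * inertia 0.01 and damping 0.2 (per-degree units) give an overdamped
      joint settling in roughly a second;
    * hard stops at +/-30 deg sagittal, +/-25 deg frontal bracket the target
      ranges of motion;
    * all noise sigmas are zero, so reference runs are deterministic.
    """
    sagittal = DofParams(
        inertia_j=0.01,
        damping_b=0.2,
        stiffness_k=0.5,
        rest_angle_deg=0.0,
        angle_min_deg=-30.0,
        angle_max_deg=30.0,
    )
    frontal = DofParams(
        inertia_j=0.01,
        damping_b=0.2,
        stiffness_k=0.5,
        rest_angle_deg=0.0,
        angle_min_deg=-25.0,
        angle_max_deg=25.0,
    )

    def actuator(dof: str, direction: int) -> ChannelActuator:
        return ChannelActuator(
            dof=dof,
            direction=direction,
            max_torque_nm=20.0,
            duty_threshold_pct=3.0,
            duty_saturation_pct=14.0,
            activation_tau_s=0.05,
        )

    return AnklePlantParams(
        dofs={"sagittal": sagittal, "frontal": frontal},
        channels={
            0: actuator("sagittal", +1),  # dorsiflexor (tibialis anterior analogue)
            1: actuator("sagittal", -1),  # plantar flexor (gastrocnemius analogue)
            2: actuator("frontal", +1),  # invertor (flexor hallucis longus analogue)
            3: actuator("frontal", -1),  # evertor (peroneus longus/brevis analogue)
        },
        noise=NoiseParams(),
    )
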