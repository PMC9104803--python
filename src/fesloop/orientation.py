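"""Joint-angle estimation from accelerometer + gyroscope streams.

A single-coefficient complementary filter blends gyro integration (trusted at
high frequency) with accelerometer gravity tilt (trusted at low frequency):

    angle <- alpha * (angle + gyro_rate * dt) + (1 - alpha) * accel_tilt

Sign convention (documented on :class:`JointAngles`): sagittal-plane
dorsiflexion and frontal-plane inversion are positive.  The sagittal axis is
driven by gyro x, the frontal axis by gyro y; magnetometer/barometer channels,
if present in an input record, are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IMUSample",
    "JointAngles",
    "FilterState",
    "UndefinedTiltError",
    "accel_inclination",
    "comp_filter_update",
    "estimate_trajectory",
    "imu_to_csv",
    "imu_from_csv",
    "wrap_angle_deg",
]

IMU_CSV_COLUMNS = [
    "timestamp_s",
    "ax_g",
    "ay_g",
    "az_g",
    "gx_dps",
    "gy_dps",
    "gz_dps",
]


class UndefinedTiltError(ValueError):
    """Raised when the accelerometer vector has zero magnitude."""


def wrap_angle_deg(deg: float) -> float:
    """Wrap an angle to (-180, 180]."""
    wrapped = -((-deg + 180.0) % 360.0 - 180.0)
    return wrapped


@dataclass(frozen=True)
class IMUSample:
    """One inertial reading: accel in g, gyro in deg/s."""

    timestamp_s: float
    accel_g: tuple[float, float, float]
    gyro_dps: tuple[float, float, float]


@dataclass(frozen=True)
class JointAngles:
    """Fused ankle angles in degrees.

    ``sagittal_deg``: dorsiflexion positive, plantar flexion negative.
    ``frontal_deg``: inversion positive, eversion negative.
    """

    sagittal_deg: float
    frontal_deg: float


@dataclass(frozen=True)
class FilterState:
    angles: JointAngles
    alpha: float
    last_timestamp_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


def accel_inclination(sample: IMUSample) -> JointAngles:
    """Gravity-referenced tilt: sagittal = atan2(ax, az), frontal = atan2(ay, az).

    Invariant to uniform scaling of the accelerometer vector.
    """
    ax, ay, az = sample.accel_g
    if ax == 0.0 and ay == 0.0 and az == 0.0:
        raise UndefinedTiltError("zero-magnitude accelerometer vector has no tilt")
    return JointAngles(
        sagittal_deg=math.degrees(math.atan2(ax, az)),
        frontal_deg=math.degrees(math.atan2(ay, az)),
    )


def comp_filter_update(state: FilterState, sample: IMUSample) -> FilterState:
    """One complementary-filter step; rejects non-monotone timestamps."""
    dt = sample.timestamp_s - state.last_timestamp_s
    if dt <= 0:
        raise ValueError(
            f"sample timestamp {sample.timestamp_s} not after {state.last_timestamp_s}"
        )
    tilt = accel_inclination(sample)
    a = state.alpha
    gx, gy, _ = sample.gyro_dps
    sag = a * (state.angles.sagittal_deg + gx * dt) + (1.0 - a) * tilt.sagittal_deg
    fro = a * (state.angles.frontal_deg + gy * dt) + (1.0 - a) * tilt.frontal_deg
    return FilterState(
        angles=JointAngles(wrap_angle_deg(sag), wrap_angle_deg(fro)),
        alpha=a,
        last_timestamp_s=sample.timestamp_s,
    )


def estimate_trajectory(samples, alpha: float) -> list[JointAngles]:
    """Fold the filter over a stream, seeding from the first sample's tilt."""
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one IMU sample")
    state = FilterState(
        angles=accel_inclination(samples[0]),
        alpha=alpha,
        last_timestamp_s=samples[0].timestamp_s,
    )
    out = [state.angles]
    for sample in samples[1:]:
        state = comp_filter_update(state, sample)
        out.append(state.angles)
    return out


def imu_to_csv(samples, path) -> None:
    rows = [
        (s.timestamp_s, *s.accel_g, *s.gyro_dps) for s in samples
    ]
    pd.DataFrame(rows, columns=IMU_CSV_COLUMNS).to_csv(path, index=False)


def imu_from_csv(path) -> list[IMUSample]:
    """Read an IMU stream; extra columns (e.g. magnetometer) are ignored."""
    df = pd.read_csv(path)
    missing = set(IMU_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"IMU CSV missing columns: {sorted(missing)}")
    t = df["timestamp_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("IMU timestamps must be strictly increasing")
    return [
        IMUSample(
            timestamp_s=float(r.timestamp_s),
            accel_g=(float(r.ax_g), float(r.ay_g), float(r.az_g)),
            gyro_dps=(float(r.gx_dps), float(r.gy_dps), float(r.gz_dps)),
        )
        for r in df.itertuples()
    ]
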