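"""Discrete PID with conditional-integration anti-windup and hard saturation.

The continuous law u = Kp*e + Ki*integral(e) + Kd*de/dt is discretised with a
backward-Euler integral (I <- I + e*dt, accumulated before the output is
formed) and a first-difference derivative on the raw error.  The output is
clamped to [u_min, u_max]; while the unsaturated output is beyond a limit and
the error keeps pushing it further out, the integrator is frozen (conditional
integration) so it cannot wind up.

Units: errors in degrees, output in signed boost duty-cycle percent.  The
derivative is unfiltered by default; an optional first-order derivative filter
can be enabled via ``PIDGains.deriv_filter_tau_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["PIDGains", "PIDState", "ControlAction", "pid_step", "pid_reset"]


@dataclass(frozen=True)
class PIDGains:
    """Controller coefficients and output limits.

    kp: duty%/deg, ki: duty%/(deg*s), kd: duty%*s/deg.  Limits are signed
    duty percent; leave them infinite for an unconstrained controller.
    """

    kp: float
    ki: float
    kd: float = 0.0
    u_min: float = -math.inf
    u_max: float = math.inf
    deriv_filter_tau_s: float | None = None  # None = raw derivative

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("gains must be >= 0")
        if not self.u_min < self.u_max:
            raise ValueError(f"need u_min < u_max, got [{self.u_min}, {self.u_max}]")
        if self.deriv_filter_tau_s is not None and self.deriv_filter_tau_s <= 0:
            raise ValueError("deriv_filter_tau_s must be > 0 when set")


@dataclass(frozen=True)
class PIDState:
    """Integrator and derivative memory between steps."""

    integral: float = 0.0  # deg*s
    prev_error: float = 0.0
    last_output: float = 0.0
    saturated: bool = False
    deriv: float = 0.0  # filtered derivative memory


@dataclass(frozen=True)
class ControlAction:
    u: float  # signed duty percent, within [u_min, u_max]
    saturated: bool


def pid_step(
    gains: PIDGains, state: PIDState, error: float, dt: float
) -> tuple[ControlAction, PIDState]:
    """Advance the controller one sample.

    The integral candidate is accumulated first (backward Euler); if the
    resulting unsaturated output lies beyond a limit while the error drives it
    further out (u' > u_max with e > 0, or u' < u_min with e < 0), the
    accumulation is discarded and the previous integral is kept.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")

    integral_cand = state.integral + error * dt
    raw_deriv = (error - state.prev_error) / dt
    if gains.deriv_filter_tau_s is None:
        deriv = raw_deriv
    else:
        tau = gains.deriv_filter_tau_s
        deriv = state.deriv + (dt / (tau + dt)) * (raw_deriv - state.deriv)

    u_unsat = gains.kp * error + gains.ki * integral_cand + gains.kd * deriv

    winding_up = (u_unsat > gains.u_max and error > 0) or (
        u_unsat < gains.u_min and error < 0
    )
    integral = state.integral if winding_up else integral_cand
    if winding_up:
        u_unsat = gains.kp * error + gains.ki * integral + gains.kd * deriv

    u = min(max(u_unsat, gains.u_min), gains.u_max)
    saturated = u != u_unsat
    action = ControlAction(u=u, saturated=saturated)
    new_state = PIDState(
        integral=integral,
        prev_error=error,
        last_output=u,
        saturated=saturated,
        deriv=deriv,
    )
    return action, new_state


def pid_reset(state: PIDState | None = None) -> PIDState:
    """Return a zeroed controller state (idempotent)."""
    return PIDState()
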