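"""Control laws: PID baseline, MIT-rule MRAC, fuzzy-PI MRAC, set-point modulation.

The adaptive laws follow the model-reference scheme: the patient output y must
track the output y_m of a fixed reference model, and the single adjustable
parameter theta multiplies the set-point to form the control signal u.

* MIT rule (plain MRAC):        dtheta/dt = -gamma * e * y_m,   e = y - y_m
* fuzzy-PI MRAC:                dtheta/dt = -m(e, de) * y_m
  where the crisp adaptation gain m replaces the fixed product gamma*e.  At
  e = de = 0 the fuzzy output is zero, so theta — and hence the oxygen flow —
  holds steady.
* set-point modulation:         r' = r + (r - y), clipped to [0, 100]
  a transient inflation (deflation) of the commanded level during undershoot
  (overshoot) that sharpens the response without moving the steady-state
  target (r' = r exactly when y = r).

The composite controller (SFPIMRAC) emits u = r' * theta, clamped to
[0, u_max]: an oxygen supply cannot be negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .fuzzy import FuzzyGainSystem, infer_gain

__all__ = [
    "MRACState",
    "PIDConfig",
    "PIDState",
    "ControllerOutputs",
    "mit_update",
    "fuzzy_adaptive_update",
    "modulate_setpoint",
    "sfpimrac_step",
    "mrac_step",
    "pid_step",
    "DEFAULT_PID",
]


@dataclass(frozen=True)
class MRACState:
    """Adaptive-controller state: adjustable parameter and error memory."""

    theta: float = 0.0
    gamma: float = 0.0  # adaptation gain (plain MRAC only)
    e_prev: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta):
            raise ValueError("theta must be finite")


def _check_finite(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not math.isfinite(v):
            raise ValueError(f"{name}={v} is not finite")


def mit_update(state: MRACState, e: float, ym: float, dt: float) -> MRACState:
    """One explicit-Euler step of the MIT rule dtheta/dt = -gamma * e * ym.

    ``e = y - ym`` is the model-following error.  The law is the negative
    gradient of the loss e^2/2 with respect to theta (up to the positive
    factor absorbed into gamma).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    _check_finite(e=e, ym=ym)
    return replace(state, theta=state.theta - state.gamma * ym * e * dt, e_prev=e)


def fuzzy_adaptive_update(
    state: MRACState,
    e: float,
    de: float,
    ym: float,
    sys: FuzzyGainSystem,
    dt: float,
    literal: bool = False,
) -> tuple[MRACState, float]:
    """One step of the fuzzy-adapted law dtheta/dt = -m(e, de) * ym.

    The fuzzy gain m replaces the gamma*e factor of the MIT integrand; with
    e = de = 0, m = 0 and theta holds ("maintain the same flow").  With
    ``literal=True`` the memoryless form theta = -m*ym is applied instead
    (provided for comparison; it cannot hold a nonzero flow at zero error).
    Returns (new state, m).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    _check_finite(e=e, de=de, ym=ym)
    m = infer_gain(e, de, sys)
    if literal:
        theta = -m * ym
    else:
        theta = state.theta - m * ym * dt
    return replace(state, theta=theta, e_prev=e), m


def modulate_setpoint(r: float, y: float) -> float:
    """Dynamic set-point r' = r + (r - y), clipped to [0, 100] % SpO2."""
    if not 0.0 <= r <= 100.0:
        raise ValueError(f"set-point r={r} must lie in [0, 100]")
    return min(max(r + (r - y), 0.0), 100.0)


@dataclass(frozen=True)
class ControllerOutputs:
    u: float       # control signal, % of full oxygen-supply scale
    r_mod: float   # modulated set-point, % SpO2
    m: float       # current fuzzy adaptation gain
    theta: float   # current adjustable parameter


def sfpimrac_step(
    state: MRACState,
    r: float,
    y: float,
    ym: float,
    sys: FuzzyGainSystem,
    dt: float,
    u_max: float = 200.0,
    literal: bool = False,
) -> tuple[ControllerOutputs, MRACState]:
    """One sample of the set-point-modulated fuzzy-PI MRAC.

    Computes e = y - ym and the backward difference de = (e - e_prev)/dt,
    updates theta through the fuzzy law, modulates the set-point, and emits
    u = r' * theta clamped to [0, u_max].
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    _check_finite(r=r, y=y, ym=ym)
    e = y - ym
    de = (e - state.e_prev) / dt
    new_state, m = fuzzy_adaptive_update(state, e, de, ym, sys, dt, literal=literal)
    r_mod = modulate_setpoint(r, y)
    u = min(max(r_mod * new_state.theta, 0.0), u_max)
    return ControllerOutputs(u=u, r_mod=r_mod, m=m, theta=new_state.theta), new_state


def mrac_step(
    state: MRACState,
    r: float,
    y: float,
    ym: float,
    dt: float,
    u_max: float = 200.0,
) -> tuple[ControllerOutputs, MRACState]:
    """One sample of the plain MIT-rule MRAC: u = r * theta."""
    if not dt > 0:
        raise ValueError("dt must be > 0")
    _check_finite(r=r, y=y, ym=ym)
    e = y - ym
    new_state = mit_update(state, e, ym, dt)
    u = min(max(r * new_state.theta, 0.0), u_max)
    return ControllerOutputs(u=u, r_mod=r, m=0.0, theta=new_state.theta), new_state


@dataclass(frozen=True)
class PIDConfig:
    """Parallel PID with output clamping and integral anti-windup."""

    kp: float = 0.0
    ki: float = 0.0
    kd: float = 0.0
    u_min: float = 0.0
    u_max: float = 200.0

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("PID gains must be >= 0")
        if not self.u_min < self.u_max:
            raise ValueError("PID output limits require u_min < u_max")


#: Baseline tuning on the composite patient model (documented hand tuning; the
#: published study names a PID baseline but gives no gains).
DEFAULT_PID = PIDConfig(kp=0.8, ki=0.25, kd=0.4)


@dataclass(frozen=True)
class PIDState:
    integral: float = 0.0
    e_prev: float = 0.0
    primed: bool = False  # first-sample guard for the derivative term


def pid_step(
    cfg: PIDConfig, r: float, y: float, state: PIDState, dt: float
) -> tuple[float, PIDState]:
    """Textbook parallel PID on the error r - y with clamping anti-windup."""
    if not dt > 0:
        raise ValueError("dt must be > 0")
    _check_finite(r=r, y=y)
    e = r - y
    integral = state.integral + e * dt
    deriv = (e - state.e_prev) / dt if state.primed else 0.0
    u = cfg.kp * e + cfg.ki * integral + cfg.kd * deriv
    if u > cfg.u_max:
        u = cfg.u_max
        integral = state.integral  # freeze the integrator while saturated
    elif u < cfg.u_min:
        u = cfg.u_min
        integral = state.integral
    return u, PIDState(integral=integral, e_prev=e, primed=True)
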