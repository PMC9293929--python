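"""Actuator fault models: pump degradation and controller dropout.

Two stress scenarios for the closed loop:

* an actuator fault that combines a multiplicative gain loss
  ``rho(t) = rho_floor + rho_span exp(-rho_rate t)`` (decaying from 1
  towards a small floor) with an additive bias
  ``phi(t) = phi_amp (1 - exp(-phi_rate t))``, applied as
  ``u_faulty = rho(t) u + phi(t)``;

* a dropout window during which the delivered input is attenuated by a
  constant factor (the pump almost stops executing commands).

Faults act on the *delivered* input only: the controller keeps seeing its
own commanded u, which is what makes these robustness tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ActuatorFaultProfile",
    "DropoutWindow",
    "multiplicative_fault",
    "additive_fault",
    "apply_actuator_fault",
    "apply_dropout",
]


@dataclass(frozen=True)
class ActuatorFaultProfile:
    """Combined multiplicative + additive actuator fault, clocked from t=0."""

    rho_floor: float = 0.01  # residual pump gain as t -> inf
    rho_span: float = 0.99  # decaying part; rho(0) = floor + span
    rho_rate: float = 0.1  # gain-loss rate [1/min]
    phi_amp: float = 0.1  # asymptotic additive bias [uU/ml/min]
    phi_rate: float = 0.1  # bias onset rate [1/min]
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.rho_floor <= 0 or self.rho_floor + self.rho_span > 1.0 + 1e-12:
            raise ValueError("rho(t) must stay in (0, 1]")
        if self.rho_span < 0 or self.rho_rate < 0:
            raise ValueError("rho_span and rho_rate must be non-negative")
        if self.phi_amp < 0 or self.phi_rate < 0:
            raise ValueError("phi_amp and phi_rate must be non-negative")


@dataclass(frozen=True)
class DropoutWindow:
    """Open time window (t_start, t_end) with input attenuated by a factor."""

    t_start: float = 240.0  # 10 A.M. on the 6 A.M. clock [min]
    t_end: float = 360.0  # noon [min]
    attenuation: float = 0.002

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("dropout window must satisfy t_start < t_end")
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in (0, 1]")


def multiplicative_fault(t: float, profile: ActuatorFaultProfile) -> float:
    """Pump gain rho(t) in (0, 1]; 1 at t=0, decaying to rho_floor."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return profile.rho_floor + profile.rho_span * math.exp(-profile.rho_rate * t)


def additive_fault(t: float, profile: ActuatorFaultProfile) -> float:
    """Additive bias phi(t) >= 0; 0 at t=0, saturating at phi_amp."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return profile.phi_amp * (1.0 - math.exp(-profile.phi_rate * t))


def apply_actuator_fault(u: float, t: float, profile: ActuatorFaultProfile) -> float:
    """Delivered input rho(t) u + phi(t); identity when the profile is disabled."""
    if not profile.enabled:
        return u
    return multiplicative_fault(t, profile) * u + additive_fault(t, profile)


def apply_dropout(u: float, t: float, window: DropoutWindow) -> float:
    """Attenuate u inside the open window (t_start, t_end), pass through outside."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if window.t_start < t < window.t_end:
        return window.attenuation * u
    return u
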