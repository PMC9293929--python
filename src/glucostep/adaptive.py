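"""Adaptive backstepping: on-line estimation of the meal disturbance.

The meal-induced glucose appearance D(t) is unknown to the controller.
The adaptive variant augments the backstepping design with an estimate
D_hat driven by the glucose tracking error,

    dD_hat/dt = delta * e1,

obtained from a Lyapunov argument: with V = sum of squared tracking
errors plus D_tilde^2 / (2 delta) (D_tilde = D - D_hat), this update
cancels the estimation-error cross term and leaves
dV/dt = -k1 e1^2 - k2 e2^2 - k3 e3^2 <= 0.

The estimate enters the first backstepping step only (the desired
insulin action); the remaining two steps are unchanged.  No projection
or leakage is applied, so D_hat may transiently overshoot the true
disturbance — expected, and visible under actuator faults.
"""

from __future__ import annotations

from dataclasses import dataclass

from .backstepping import ControllerGains, desired_x2
from .model import PatientParams

__all__ = ["AdaptiveState", "adaptive_update", "adaptive_desired_x2", "lyapunov_v3"]


@dataclass
class AdaptiveState:
    """Running disturbance estimate and its adaptation gain.

    ``delta`` scales how fast the estimate integrates the glucose error;
    ``d_hat`` starts at 0 by default (uninformative prior).
    """

    delta: float = 0.001
    d_hat: float = 0.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("adaptive gain delta must be positive")


def adaptive_update(d_hat: float, e1: float, delta: float, dt: float) -> float:
    """One forward-Euler step of the adaptive rule dD_hat/dt = delta e1."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return d_hat + delta * e1 * dt


def adaptive_desired_x2(
    x1: float,
    x1d: float,
    x1d_dot: float,
    gains: ControllerGains,
    params: PatientParams,
    d_hat: float,
) -> float:
    """Desired insulin action with the disturbance estimate compensated.

    Identical algebra to the non-adaptive first step with ``+ D_hat``
    inside the bracket; delegates to that implementation.
    """
    return desired_x2(x1, x1d, x1d_dot, gains, params, d_hat=d_hat)


def lyapunov_v3(e1: float, e2: float, e3: float, d_tilde: float, delta: float) -> float:
    """Composite Lyapunov value V3 = (e1^2 + e2^2 + e3^2)/2 + d_tilde^2/(2 delta)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    return 0.5 * (e1 * e1 + e2 * e2 + e3 * e3) + d_tilde * d_tilde / (2.0 * delta)
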