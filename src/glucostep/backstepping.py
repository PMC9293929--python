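"""Three-step backstepping control law for the minimal model.

The plant is in strict-feedback form (G is driven by X, X by I, I by u),
so the controller is built recursively: a desired insulin action x2d
stabilises the glucose tracking error e1 = G - G_d, a desired plasma
insulin x3d stabilises e2 = X - x2d, and the infusion rate u stabilises
e3 = I - x3d.  Each step assigns first-order error dynamics
``de_i/dt = -k_i e_i`` with a positive gain k_i.

The desired-state time derivatives that the second and third steps need
are not available in closed form (they involve the unknown meal
disturbance), so the sampled controller estimates them by backward
differences on its own grid — zero at the first sample.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import G_GUARD, GuardError, PatientParams

__all__ = [
    "ControllerGains",
    "desired_x2",
    "desired_x3",
    "control_law",
    "hold_derivative",
]


@dataclass(frozen=True)
class ControllerGains:
    """Backstepping gains k1, k2, k3 [1/min]; each must be positive."""

    k1: float = 0.43
    k2: float = 0.46
    k3: float = 0.62

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.k3 <= 0:
            raise ValueError("all backstepping gains must be strictly positive")


def desired_x2(
    x1: float,
    x1d: float,
    x1d_dot: float,
    gains: ControllerGains,
    params: PatientParams,
    d_hat: float = 0.0,
) -> float:
    """Desired insulin action x2d [1/min] stabilising the glucose error.

    Solving the glucose equation for the X that enforces
    ``de1/dt = -k1 e1`` gives

        x2d = [ -p1 (x1 - Gb) - dG_d/dt + k1 (x1 - x1d) + D_hat ] / x1

    The pure backstepping law cannot use the unknown disturbance and
    passes ``d_hat = 0``; the adaptive variant passes its running
    estimate.  Requires x1 above the degeneracy guard (division by x1).
    """
    if x1 <= G_GUARD:
        raise GuardError(f"glucose {x1:.3g} mg/dl at or below guard {G_GUARD}")
    return (
        -params.p1 * (x1 - params.Gb) - x1d_dot + gains.k1 * (x1 - x1d) + d_hat
    ) / x1


def desired_x3(
    x2: float,
    x2d: float,
    x2d_dot: float,
    gains: ControllerGains,
    params: PatientParams,
) -> float:
    """Desired plasma insulin x3d [uU/ml] stabilising e2 = x2 - x2d.

    x3d = Ib + [ p2 x2 + dx2d/dt - k2 (x2 - x2d) ] / p3
    """
    return params.Ib + (params.p2 * x2 + x2d_dot - gains.k2 * (x2 - x2d)) / params.p3


def control_law(
    x3: float,
    x3d: float,
    x3d_dot: float,
    gains: ControllerGains,
    params: PatientParams,
    nonnegative: bool = False,
) -> float:
    """Insulin infusion rate u [uU/ml/min] stabilising e3 = x3 - x3d.

    u = n (x3 - Ib) + dx3d/dt - k3 (x3 - x3d), optionally clamped at zero
    when ``nonnegative`` is set (a physical pump cannot extract insulin).
    """
    u = params.n * (x3 - params.Ib) + x3d_dot - gains.k3 * (x3 - x3d)
    if nonnegative and u < 0.0:
        return 0.0
    return u


def hold_derivative(history, dt: float) -> float:
    """Backward-difference derivative of a sampled signal.

    Returns ``(history[-1] - history[-2]) / dt``, or 0 when only one
    sample exists (controller start-up).  Exact for affine signals.
    """
    if dt <= 0:
        raise ValueError("sampling interval dt must be positive")
    if len(history) < 1:
        raise ValueError("need at least one sample")
    if len(history) < 2:
        return 0.0
    return (history[-1] - history[-2]) / dt
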