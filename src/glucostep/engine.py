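"""Closed-loop simulation engine: sampled controller, continuous plant.

One 24-hour run wires together the minimal-model plant, the meal
schedule, the reference trajectory, one of the two control laws (or no
control at all), the adaptive disturbance estimator, and optional
actuator-fault / dropout transforms.

The controller is a sampled-data system: every ``controller_step``
minutes it reads the plant state, computes the backstepping cascade and
the infusion rate, updates the disturbance estimate (adaptive mode), and
holds the resulting input constant while the plant's ODE is integrated
continuously over the interval (zero-order hold).  Fault transforms are
applied after the control law and before the plant, in the order
actuator fault then dropout; the controller never sees the delivered
input.  Everything is deterministic — identical scenarios give identical
outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import ode

from .adaptive import adaptive_update, lyapunov_v3
from .backstepping import ControllerGains, control_law, desired_x2, desired_x3
from .faults import ActuatorFaultProfile, DropoutWindow, apply_actuator_fault, apply_dropout
from .model import (
    G_GUARD,
    GuardError,
    MealSchedule,
    PatientParams,
    PlantState,
    ReferenceTrajectory,
    meal_disturbance,
    reference_derivatives,
    reference_value,
)

__all__ = ["Scenario", "SimulationResult", "simulate", "lyapunov_series"]

MODES = ("backstepping", "adaptive", "none")
DERIVATIVE_SCHEMES = ("hold", "analytic")

#: CSV column order shared with the I/O layer.
RESULT_COLUMNS = (
    "time_min",
    "G",
    "X",
    "I",
    "u_commanded",
    "u_applied",
    "D_true",
    "D_hat",
    "G_d",
)


@dataclass(frozen=True)
class Scenario:
    """Complete description of one closed-loop experiment."""

    params: PatientParams = field(default_factory=PatientParams)
    meals: MealSchedule = field(default_factory=MealSchedule)
    reference: ReferenceTrajectory = field(default_factory=ReferenceTrajectory)
    gains: ControllerGains = field(default_factory=ControllerGains)
    delta: float = 0.001  # adaptive gain
    mode: str = "adaptive"  # backstepping | adaptive | none (u == 0)
    fault: Optional[ActuatorFaultProfile] = None
    dropout: Optional[DropoutWindow] = None
    initial: PlantState = field(default_factory=lambda: PlantState(150.0, 0.0, 100.0))
    horizon: float = 1440.0  # [min]
    controller_step: float = 0.1  # [min]
    report_step: float = 1.0  # [min]
    rtol: float = 1e-8
    atol: float = 1e-10
    derivative_scheme: str = "hold"  # hold (backward difference) | analytic
    nonnegative_insulin: bool = False
    d_hat0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.derivative_scheme not in DERIVATIVE_SCHEMES:
            raise ValueError(f"derivative_scheme must be one of {DERIVATIVE_SCHEMES}")
        if self.horizon <= 0 or self.controller_step <= 0 or self.report_step <= 0:
            raise ValueError("horizon and step sizes must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        stride = self.report_step / self.controller_step
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError("report_step must be an integer multiple of controller_step")

    def refined(self, factor: float = 0.5) -> "Scenario":
        """A copy with the controller step and solver tolerances scaled down."""
        return replace(
            self,
            controller_step=self.controller_step * factor,
            rtol=self.rtol * factor,
            atol=self.atol * factor,
        )


@dataclass
class SimulationResult:
    """Aligned time series from one run, on the uniform report grid.

    ``u_commanded`` is the controller's output; ``u_applied`` is what the
    plant received after faults.  ``e1..e3``, ``x2d``, ``x3d`` are the
    controller's internal cascade, recorded for Lyapunov diagnostics.
    """

    t: np.ndarray
    G: np.ndarray
    X: np.ndarray
    I: np.ndarray
    u_commanded: np.ndarray
    u_applied: np.ndarray
    D_true: np.ndarray
    D_hat: np.ndarray
    G_d: np.ndarray
    x2d: np.ndarray
    x3d: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray
    scenario: Scenario

    def to_frame(self):
        """The canonical report table (pandas DataFrame, one row per minute)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.t,
                "G": self.G,
                "X": self.X,
                "I": self.I,
                "u_commanded": self.u_commanded,
                "u_applied": self.u_applied,
                "D_true": self.D_true,
                "D_hat": self.D_hat,
                "G_d": self.G_d,
            }
        )


def simulate(scenario: Scenario) -> SimulationResult:
    """Run one closed-loop experiment and return its report-grid series.

    Raises :class:`~glucostep.model.GuardError` if glucose falls below the
    degeneracy guard and ``RuntimeError`` on integrator failure or
    non-finite states.
    """
    sc = scenario
    p = sc.params
    dt = sc.controller_step
    n_ctrl = int(round(sc.horizon / dt))
    stride = int(round(sc.report_step / dt))
    n_rep = n_ctrl // stride + 1

    u_hold = [0.0]  # delivered input, mutated between integrator calls

    def rhs(t, y):
        G, X, I = y
        D = meal_disturbance(t, sc.meals)
        return [
            -p.p1 * (G - p.Gb) - G * X + D,
            -p.p2 * X + p.p3 * (I - p.Ib),
            -p.n * (I - p.Ib) + u_hold[0],
        ]

    r = ode(rhs)
    r.set_integrator("dopri5", rtol=sc.rtol, atol=sc.atol, nsteps=100000)
    y = sc.initial.as_array()
    r.set_initial_value(y, 0.0)

    cols = {
        name: np.empty(n_rep)
        for name in (
            "t", "G", "X", "I", "u_commanded", "u_applied",
            "D_true", "D_hat", "G_d", "x2d", "x3d", "e1", "e2", "e3",
        )
    }

    d_hat = sc.d_hat0
    prev_x2d: Optional[float] = None
    prev_x3d: Optional[float] = None
    i_rep = 0

    for k in range(n_ctrl + 1):
        t = k * dt
        G, X, I = (float(v) for v in y)
        if not np.all(np.isfinite(y)):
            raise RuntimeError(f"non-finite plant state at t={t:.2f} min")
        if G < G_GUARD:
            raise GuardError(
                f"glucose {G:.3g} mg/dl below guard {G_GUARD} at t={t:.2f} min"
            )

        x1d = reference_value(t, sc.reference)
        x1d_dot, x1d_ddot = reference_derivatives(t, sc.reference)
        amp = sc.reference.G0 - sc.reference.Ginf
        x1d_d3 = -amp / sc.reference.tau**3 * np.exp(-t / sc.reference.tau)
        e1 = G - x1d
        D_now = meal_disturbance(t, sc.meals)

        if sc.mode == "none":
            u = 0.0
            x2d = x3d = 0.0
            e2 = e3 = 0.0
            dh_used = d_hat
        else:
            dh_used = d_hat if sc.mode == "adaptive" else 0.0
            x2d = desired_x2(G, x1d, x1d_dot, sc.gains, p, d_hat=dh_used)
            if sc.derivative_scheme == "analytic":
                # Chain rule through the whole cascade, with the unknown D
                # replaced everywhere by the controller's best substitute
                # (D_hat in adaptive mode, 0 in pure backstepping).  This is
                # what makes the controller blind to meals except through
                # the glucose error itself.
                k1 = sc.gains.k1
                dh_dot = sc.delta * e1 if sc.mode == "adaptive" else 0.0
                f1 = -p.p1 * (G - p.Gb) - G * X + dh_used  # estimated dG/dt
                f2 = -p.p2 * X + p.p3 * (I - p.Ib)  # exact dX/dt
                f1_dot = -p.p1 * f1 - (f1 * X + G * f2) + dh_dot
                num = -p.p1 * (G - p.Gb) - x1d_dot + k1 * (G - x1d) + dh_used
                num_dot = -p.p1 * f1 - x1d_ddot + k1 * (f1 - x1d_dot) + dh_dot
                dh_ddot = sc.delta * (f1 - x1d_dot) if sc.mode == "adaptive" else 0.0
                num_ddot = -p.p1 * f1_dot - x1d_d3 + k1 * (f1_dot - x1d_ddot) + dh_ddot
                x2d_dot = num_dot / G - num * f1 / (G * G)
                x2d_ddot = (
                    num_ddot / G
                    - 2.0 * num_dot * f1 / (G * G)
                    - num * f1_dot / (G * G)
                    + 2.0 * num * f1 * f1 / (G * G * G)
                )
                e2 = X - x2d
                x3d = desired_x3(X, x2d, x2d_dot, sc.gains, p)
                x3d_dot = (p.p2 * f2 + x2d_ddot - sc.gains.k2 * (f2 - x2d_dot)) / p.p3
            else:
                x2d_dot = 0.0 if prev_x2d is None else (x2d - prev_x2d) / dt
                e2 = X - x2d
                x3d = desired_x3(X, x2d, x2d_dot, sc.gains, p)
                x3d_dot = 0.0 if prev_x3d is None else (x3d - prev_x3d) / dt
            e3 = I - x3d
            u = control_law(I, x3d, x3d_dot, sc.gains, p, sc.nonnegative_insulin)
            if sc.mode == "adaptive":
                d_hat = adaptive_update(d_hat, e1, sc.delta, dt)
            prev_x2d, prev_x3d = x2d, x3d

        u_app = u
        if sc.fault is not None:
            u_app = apply_actuator_fault(u_app, t, sc.fault)
        if sc.dropout is not None:
            u_app = apply_dropout(u_app, t, sc.dropout)

        if k % stride == 0:
            for name, val in (
                ("t", t), ("G", G), ("X", X), ("I", I),
                ("u_commanded", u), ("u_applied", u_app),
                ("D_true", D_now), ("D_hat", dh_used), ("G_d", x1d),
                ("x2d", x2d), ("x3d", x3d), ("e1", e1), ("e2", e2), ("e3", e3),
            ):
                cols[name][i_rep] = val
            i_rep += 1

        if k < n_ctrl:
            u_hold[0] = u_app
            r.integrate(t + dt)
            if not r.successful():
                raise RuntimeError(f"ODE integration failed at t={t:.2f} min")
            y = r.y

    return SimulationResult(
        t=cols["t"], G=cols["G"], X=cols["X"], I=cols["I"],
        u_commanded=cols["u_commanded"], u_applied=cols["u_applied"],
        D_true=cols["D_true"], D_hat=cols["D_hat"], G_d=cols["G_d"],
        x2d=cols["x2d"], x3d=cols["x3d"],
        e1=cols["e1"], e2=cols["e2"], e3=cols["e3"],
        scenario=scenario,
    )


def lyapunov_series(result: SimulationResult, scenario: Optional[Scenario] = None) -> np.ndarray:
    """Composite Lyapunov value V3 along an adaptive run's report grid.

    V3 = (e1^2 + e2^2 + e3^2)/2 + (D - D_hat)^2 / (2 delta), with the true
    disturbance known to the engine (diagnostic, not available to the
    controller).  Raises if the run was not adaptive.
    """
    sc = scenario if scenario is not None else result.scenario
    if sc.mode != "adaptive":
        raise ValueError("Lyapunov diagnostics require an adaptive-mode run")
    d_tilde = result.D_true - result.D_hat
    return np.array(
        [
            lyapunov_v3(e1, e2, e3, dt_, sc.delta)
            for e1, e2, e3, dt_ in zip(result.e1, result.e2, result.e3, d_tilde)
        ]
    )
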