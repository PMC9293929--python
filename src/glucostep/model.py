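"""Bergman minimal-model plant, meal disturbances, and the glucose reference.

The plant is the classic three-state minimal model of glucose--insulin
kinetics:

    dG/dt = -p1 (G - Gb) - G X + D(t)
    dX/dt = -p2 X + p3 (I - Ib)
    dI/dt = -n (I - Ib) + u(t)

with G plasma glucose [mg/dl], X remote (interstitial) insulin action
[1/min], I plasma insulin [uU/ml], u the insulin infusion rate
[uU/ml/min] and D(t) the rate of glucose appearance from meals
[mg/dl/min].  Meals are modelled as decaying exponentials A exp(-B t)
clocked from each meal's onset; overlapping tails are summed by default
(physical additivity of glucose appearance), with a reset variant
available for sensitivity checks.

The tracking reference is an exponential decay from the initial glucose
towards a set point, G_d(t) = Ginf + (G0 - Ginf) exp(-t/tau), with
closed-form first and second derivatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "G_GUARD",
    "GuardError",
    "PatientParams",
    "PlantState",
    "MealEvent",
    "MealSchedule",
    "ReferenceTrajectory",
    "meal_disturbance",
    "plant_rhs",
    "reference_value",
    "reference_derivatives",
    "basal_equilibrium",
]

#: Glucose floor [mg/dl] below which a trajectory is treated as degenerate
#: (the control laws divide by G).
G_GUARD = 1.0


class GuardError(RuntimeError):
    """Raised when glucose falls below the degeneracy guard."""


@dataclass(frozen=True)
class PatientParams:
    """Minimal-model rate constants and basal levels for one patient.

    Defaults are the nominal type-1 diabetic parameter set: the
    insulin-independent uptake rate ``p1`` is zero (no endogenous glucose
    effectiveness), so untreated glucose is driven purely by meals once
    insulin action has decayed.
    """

    p1: float = 0.0  # insulin-independent glucose uptake [1/min]
    p2: float = 0.0142  # decay of insulin action [1/min]
    p3: float = 1.5e-5  # insulin-dependent uptake gain [ml/uU/min]
    n: float = 0.2814  # insulin clearance [1/min]
    Gb: float = 90.0  # basal glucose [mg/dl]
    Ib: float = 7.0  # basal insulin [uU/ml]

    def __post_init__(self) -> None:
        if self.p2 <= 0 or self.p3 <= 0 or self.n <= 0:
            raise ValueError("p2, p3 and n must be strictly positive")
        if self.p1 < 0:
            raise ValueError("p1 must be non-negative")
        if self.Gb <= 0:
            raise ValueError("basal glucose Gb must be positive")
        if self.Ib < 0:
            raise ValueError("basal insulin Ib must be non-negative")


@dataclass(frozen=True)
class PlantState:
    """Plant state: glucose G [mg/dl], insulin action X [1/min], insulin I [uU/ml]."""

    G: float
    X: float = 0.0
    I: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.X, self.I], dtype=float)


@dataclass(frozen=True)
class MealEvent:
    """One meal: glucose appearance A exp(-B (t - t_onset)) for t >= t_onset."""

    t_onset: float  # minutes from simulation start
    A: float  # peak appearance rate [mg/dl/min]
    B: float = 0.01  # decay rate [1/min]

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("meal amplitude A and decay B must be positive")
        if self.t_onset < 0:
            raise ValueError("meal onset must be non-negative")


@dataclass(frozen=True)
class MealSchedule:
    """An ordered day of meals plus the tail-superposition convention.

    ``superposition='sum'`` adds every active meal exponential (default);
    ``'reset'`` keeps only the most recent meal, discarding earlier tails.
    """

    meals: tuple[MealEvent, ...] = ()
    superposition: str = "sum"

    def __init__(self, meals: Sequence[MealEvent] = (), superposition: str = "sum"):
        meals = tuple(meals)
        onsets = [m.t_onset for m in meals]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("meal onsets must be strictly increasing")
        if superposition not in ("sum", "reset"):
            raise ValueError("superposition must be 'sum' or 'reset'")
        object.__setattr__(self, "meals", meals)
        object.__setattr__(self, "superposition", superposition)

    def __iter__(self):
        return iter(self.meals)

    def __len__(self) -> int:
        return len(self.meals)


@dataclass(frozen=True)
class ReferenceTrajectory:
    """Exponential glucose reference G_d(t) = Ginf + (G0 - Ginf) exp(-t/tau)."""

    G0: float = 150.0  # initial glucose [mg/dl]
    Ginf: float = 100.0  # asymptotic set point [mg/dl]
    tau: float = 100.0  # decay time constant [min]

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("reference time constant tau must be positive")

    def value(self, t):
        return reference_value(t, self)

    def derivatives(self, t):
        return reference_derivatives(t, self)


def meal_disturbance(t: float, schedule: MealSchedule) -> float:
    """Meal-induced glucose appearance rate D(t) [mg/dl/min].

    Each meal contributes ``A exp(-B (t - t_onset))`` from its onset.  Under
    the default ``'sum'`` convention contributions of all past meals are
    added; under ``'reset'`` only the most recent meal counts.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    active = [m for m in schedule if t >= m.t_onset]
    if not active:
        return 0.0
    if schedule.superposition == "reset":
        active = active[-1:]
    return sum(m.A * math.exp(-m.B * (t - m.t_onset)) for m in active)


def plant_rhs(
    state: PlantState,
    u: float,
    D: float,
    params: PatientParams,
) -> tuple[float, float, float]:
    """Time derivative (dG, dX, dI) of the minimal model at one instant."""
    if state.G < G_GUARD:
        raise GuardError(
            f"glucose {state.G:.3g} mg/dl below guard {G_GUARD}; trajectory degenerate"
        )
    dG = -params.p1 * (state.G - params.Gb) - state.G * state.X + D
    dX = -params.p2 * state.X + params.p3 * (state.I - params.Ib)
    dI = -params.n * (state.I - params.Ib) + u
    return (dG, dX, dI)


def reference_value(t, traj: ReferenceTrajectory):
    """Reference glucose G_d(t) [mg/dl]; accepts scalar or array t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = traj.Ginf + (traj.G0 - traj.Ginf) * np.exp(-t / traj.tau)
    return float(out) if out.ndim == 0 else out


def reference_derivatives(t, traj: ReferenceTrajectory):
    """Analytic (dG_d/dt, d2G_d/dt2) of the exponential reference."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    amp = traj.G0 - traj.Ginf
    e = np.exp(-t / traj.tau)
    d1 = -amp / traj.tau * e
    d2 = amp / traj.tau**2 * e
    if d1.ndim == 0:
        return float(d1), float(d2)
    return d1, d2


def basal_equilibrium(params: PatientParams) -> PlantState:
    """The plant's fixed point with no input and no meals: (Gb, 0, Ib)."""
    return PlantState(G=params.Gb, X=0.0, I=params.Ib)
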