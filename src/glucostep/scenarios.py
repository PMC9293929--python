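"""Preset scenarios: the nominal day and the published stress studies.

The nominal day starts at 6 A.M. from a fasting state (G=150, X=0,
I=100), with unannounced meals at 8 A.M. (breakfast, A=0.4), 2 P.M.
(lunch, A=0.6) and 8 P.M. (dinner, A=0.5), all with decay B=0.01/min,
over a 1440-min horizon.  Controller gains are 0.43/0.46/0.62 with
adaptive gain 0.001; the dropout study uses 0.45/0.45/1.5 with 0.007.
"""

from __future__ import annotations

from dataclasses import replace

from .backstepping import ControllerGains
from .engine import Scenario
from .faults import ActuatorFaultProfile, DropoutWindow
from .model import MealEvent, MealSchedule, PlantState, ReferenceTrajectory

__all__ = [
    "nominal_meals",
    "nominal_scenario",
    "preset",
    "PRESET_NAMES",
    "MULTI_IC_G0",
]

BREAKFAST_T, LUNCH_T, DINNER_T = 120.0, 480.0, 840.0  # minutes after 6 A.M.

#: Initial-glucose sweep for the multi-initial-condition study; 320 mg/dl is
#: the harshest start the published discussion quotes.
MULTI_IC_G0 = (150.0, 200.0, 250.0, 320.0)


def nominal_meals() -> MealSchedule:
    """Breakfast / lunch / dinner with lunch largest, dinner second."""
    return MealSchedule(
        [
            MealEvent(t_onset=BREAKFAST_T, A=0.4, B=0.01),
            MealEvent(t_onset=LUNCH_T, A=0.6, B=0.01),
            MealEvent(t_onset=DINNER_T, A=0.5, B=0.01),
        ]
    )


def nominal_scenario(mode: str = "adaptive", G0: float = 150.0) -> Scenario:
    """The nominal 24-h day under the requested control mode.

    The reference trajectory's initial value is matched to the initial
    glucose so tracking starts with zero error.
    """
    return Scenario(
        meals=nominal_meals(),
        reference=ReferenceTrajectory(G0=G0, Ginf=100.0, tau=100.0),
        gains=ControllerGains(k1=0.43, k2=0.46, k3=0.62),
        delta=0.001,
        mode=mode,
        initial=PlantState(G=G0, X=0.0, I=100.0),
        label=f"nominal-{mode}" if G0 == 150.0 else f"nominal-{mode}-G0={G0:g}",
    )


def _dropout_scenario(mode: str) -> Scenario:
    base = nominal_scenario(mode)
    return replace(
        base,
        gains=ControllerGains(k1=0.45, k2=0.45, k3=1.5),
        delta=0.007,
        dropout=DropoutWindow(t_start=240.0, t_end=360.0, attenuation=0.002),
        label=f"dropout-{mode}",
    )


def preset(name: str) -> Scenario | list[Scenario]:
    """Named experiment; ``multi-ic`` returns one scenario per initial glucose."""
    if name == "nominal-adaptive":
        return nominal_scenario("adaptive")
    if name == "nominal-backstepping":
        return nominal_scenario("backstepping")
    if name == "untreated":
        return replace(nominal_scenario("none"), label="untreated")
    if name == "faults-adaptive":
        return replace(
            nominal_scenario("adaptive"), fault=ActuatorFaultProfile(), label="faults-adaptive"
        )
    if name == "faults-backstepping":
        return replace(
            nominal_scenario("backstepping"),
            fault=ActuatorFaultProfile(),
            label="faults-backstepping",
        )
    if name == "dropout-adaptive":
        return _dropout_scenario("adaptive")
    if name == "dropout-backstepping":
        return _dropout_scenario("backstepping")
    if name == "multi-ic":
        return [nominal_scenario("adaptive", G0=g0) for g0 in MULTI_IC_G0]
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


PRESET_NAMES = (
    "nominal-adaptive",
    "nominal-backstepping",
    "untreated",
    "faults-adaptive",
    "faults-backstepping",
    "dropout-adaptive",
    "dropout-backstepping",
    "multi-ic",
)
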