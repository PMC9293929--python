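"""Plant dynamics, meal disturbance and reference-trajectory behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucostep import (
    MealEvent,
    MealSchedule,
    PatientParams,
    PlantState,
    ReferenceTrajectory,
    basal_equilibrium,
    meal_disturbance,
    plant_rhs,
    reference_derivatives,
    reference_value,
)
from glucostep.model import GuardError

NOMINAL = PatientParams()


def day_meals(superposition="sum"):
    return MealSchedule(
        [MealEvent(120, 0.4, 0.01), MealEvent(480, 0.6, 0.01), MealEvent(840, 0.5, 0.01)],
        superposition=superposition,
    )


class TestMealDisturbance:
    def test_before_first_meal_is_zero(self):
        assert meal_disturbance(60.0, day_meals()) == 0.0

    def test_onset_value_equals_amplitude_plus_tails(self):
        # At lunch onset the lunch term contributes exactly A = 0.6.
        lunch_only = MealSchedule([MealEvent(480, 0.6, 0.01)])
        assert meal_disturbance(480.0, lunch_only) == pytest.approx(0.6)

    def test_superposition_sums_decaying_tails(self):
        # Closed form per meal: lunch 0.6 e^{-1} plus the breakfast tail.
        expected = 0.6 * math.exp(-0.01 * 100) + 0.4 * math.exp(-0.01 * 460)
        assert meal_disturbance(580.0, day_meals()) == pytest.approx(expected, rel=1e-12)

    def test_reset_mode_keeps_only_latest_meal(self):
        expected = 0.6 * math.exp(-0.01 * 100)
        assert meal_disturbance(580.0, day_meals("reset")) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_and_decreasing_between_onsets(self):
        sched = day_meals()
        t = np.linspace(121, 479, 500)
        D = np.array([meal_disturbance(float(x), sched) for x in t])
        assert np.all(D >= 0)
        assert np.all(np.diff(D) < 0)

    def test_onsets_must_increase(self):
        with pytest.raises(ValueError):
            MealSchedule([MealEvent(480, 0.6), MealEvent(120, 0.4)])


class TestPlantRhs:
    def test_basal_state_is_fixed_point(self):
        assert plant_rhs(basal_equilibrium(NOMINAL), 0.0, 0.0, NOMINAL) == (0.0, 0.0, 0.0)

    def test_hand_evaluated_derivative(self):
        # G=150, X=0, I=100 with nominal parameters (p1 = 0).
        dG, dX, dI = plant_rhs(PlantState(150.0, 0.0, 100.0), 0.0, 0.0, NOMINAL)
        assert dG == pytest.approx(0.0)
        assert dX == pytest.approx(1.395e-3, rel=1e-12)
        assert dI == pytest.approx(-26.1702, rel=1e-12)

    def test_glucose_neutral_without_insulin_action(self):
        # p1 = 0 makes dG/dt = -G X + D; with X = 0 and D = 0 glucose holds.
        dG, _, _ = plant_rhs(PlantState(91.0, 0.0, NOMINAL.Ib), 0.0, 0.0, NOMINAL)
        assert dG == 0.0

    def test_guard_on_degenerate_glucose(self):
        with pytest.raises(GuardError):
            plant_rhs(PlantState(0.5, 0.0, 7.0), 0.0, 0.0, NOMINAL)

    @settings(max_examples=50, derandomize=True)
    @given(
        p1=st.floats(0, 0.1),
        p2=st.floats(1e-3, 0.1),
        p3=st.floats(1e-6, 1e-3),
        n=st.floats(0.01, 1.0),
        Gb=st.floats(50, 200),
        Ib=st.floats(0, 30),
    )
    def test_basal_fixed_point_for_any_parameters(self, p1, p2, p3, n, Gb, Ib):
        params = PatientParams(p1=p1, p2=p2, p3=p3, n=n, Gb=Gb, Ib=Ib)
        assert plant_rhs(basal_equilibrium(params), 0.0, 0.0, params) == (0.0, 0.0, 0.0)


class TestReference:
    TRAJ = ReferenceTrajectory(G0=150.0, Ginf=100.0, tau=100.0)

    def test_initial_and_asymptotic_values(self):
        assert reference_value(0.0, self.TRAJ) == pytest.approx(150.0)
        assert reference_value(1e7, self.TRAJ) == pytest.approx(100.0)

    def test_closed_form_at_one_time_constant(self):
        assert reference_value(100.0, self.TRAJ) == pytest.approx(100 + 50 / math.e, rel=1e-12)

    def test_analytic_derivatives(self):
        d1, d2 = reference_derivatives(0.0, self.TRAJ)
        assert d1 == pytest.approx(-0.5)
        assert d2 == pytest.approx(0.005)
        d1_inf, d2_inf = reference_derivatives(1e7, self.TRAJ)
        assert d1_inf == pytest.approx(0.0, abs=1e-12)
        assert d2_inf == pytest.approx(0.0, abs=1e-12)

    def test_constant_reference_has_zero_derivatives(self):
        flat = ReferenceTrajectory(G0=100.0, Ginf=100.0, tau=100.0)
        assert reference_derivatives(123.0, flat) == (0.0, 0.0)

    def test_monotone_decreasing_and_bounded(self):
        t = np.linspace(0, 1440, 1000)
        g = reference_value(t, self.TRAJ)
        assert np.all(np.diff(g) < 0)
        assert g.min() >= self.TRAJ.Ginf and g.max() <= self.TRAJ.G0

    def test_derivative_matches_central_difference(self):
        h = 1e-3
        for t in (10.0, 250.0, 900.0):
            num = (reference_value(t + h, self.TRAJ) - reference_value(t - h, self.TRAJ)) / (2 * h)
            ana, _ = reference_derivatives(t, self.TRAJ)
            assert ana == pytest.approx(num, rel=1e-6)


@pytest.mark.parametrize(
    "kwargs",
    [dict(p2=-1.0), dict(p3=0.0), dict(n=0.0), dict(Gb=-5.0), dict(p1=-0.1)],
)
def test_invalid_patient_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        PatientParams(**kwargs)
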