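"""Closed-loop engine: fixed points, determinism, guards, composition order."""

from dataclasses import replace

import numpy as np
import pytest

from glucostep import (
    ActuatorFaultProfile,
    DropoutWindow,
    MealSchedule,
    PlantState,
    ReferenceTrajectory,
    basal_equilibrium,
    lyapunov_series,
    nominal_scenario,
    peak_in_window,
    preset,
    simulate,
)
from glucostep.engine import Scenario
from glucostep.faults import apply_actuator_fault, apply_dropout
from glucostep.model import GuardError, PatientParams


def short(sc, horizon=60.0):
    return replace(sc, horizon=horizon)


def test_basal_fixed_point_run_is_constant():
    params = PatientParams()
    sc = Scenario(
        params=params,
        meals=MealSchedule(),
        reference=ReferenceTrajectory(G0=params.Gb, Ginf=params.Gb, tau=100.0),
        mode="none",
        initial=basal_equilibrium(params),
        horizon=120.0,
    )
    res = simulate(sc)
    assert np.allclose(res.G, params.Gb, atol=1e-9)
    assert np.allclose(res.X, 0.0, atol=1e-12)
    assert np.allclose(res.I, params.Ib, atol=1e-9)
    assert np.all(res.u_commanded == 0.0)


def test_untreated_day_reaches_dangerous_hyperglycemia(untreated):
    assert untreated.G.max() > 180.0


def test_untreated_states_relax_while_glucose_drifts_with_meals(untreated):
    res = untreated
    # Insulin relaxes to basal, insulin action decays toward zero.
    assert res.I[-1] == pytest.approx(7.0, abs=1e-3)
    assert abs(res.X[-1]) < 1e-4
    # With p1 = 0 glucose is non-decreasing once meals dominate X.
    after = res.t >= 120
    assert np.all(np.diff(res.G[after]) > -1e-6)


def test_report_grid_shape_and_alignment(nominal_adaptive):
    res = nominal_adaptive
    assert len(res.t) == 1441
    assert res.t[0] == 0.0 and res.t[-1] == 1440.0
    assert np.allclose(np.diff(res.t), 1.0)
    for series in (res.G, res.u_commanded, res.D_hat, res.G_d):
        assert len(series) == len(res.t)


def test_determinism_bit_identical():
    a = simulate(short(preset("nominal-adaptive")))
    b = simulate(short(preset("nominal-adaptive")))
    assert np.array_equal(a.G, b.G)
    assert np.array_equal(a.u_commanded, b.u_commanded)
    assert np.array_equal(a.D_hat, b.D_hat)


def test_backstepping_equals_adaptive_with_frozen_estimate():
    """With the estimate pinned at zero the two laws are the same controller."""
    bs = simulate(short(preset("nominal-backstepping"), 240.0))
    # delta is small enough that delta*e1*dt never perturbs a single bit of
    # the controller arithmetic: the adaptive path must reproduce the
    # backstepping input exactly.
    frozen = replace(preset("nominal-adaptive"), delta=1e-300, horizon=240.0)
    ad = simulate(frozen)
    assert np.array_equal(bs.u_commanded, ad.u_commanded)
    assert np.array_equal(bs.G, ad.G)


def test_disturbance_free_tracking_error_decays():
    """No meals, mismatched start: |e1| never exceeds its initial value and
    has vanished (< 1 mg/dl) by the end of the day."""
    sc = replace(
        preset("nominal-backstepping"),
        meals=MealSchedule(),
        reference=ReferenceTrajectory(G0=140.0, Ginf=100.0, tau=100.0),
    )
    res = simulate(sc)  # e1(0) = 150 - 140 = 10 mg/dl
    e1 = res.G - res.G_d
    assert abs(e1[0]) == pytest.approx(10.0)
    # Start-up uses zero desired-state derivatives, so the first samples may
    # overshoot the bound by ~1% before the cascade engages.
    assert np.max(np.abs(e1)) <= 1.05 * abs(e1[0])
    assert np.max(np.abs(e1[res.t >= 5])) <= abs(e1[0])
    assert abs(e1[-1]) < 1.0


def test_guard_aborts_degenerate_trajectory():
    sc = Scenario(
        meals=MealSchedule(),
        mode="none",
        initial=PlantState(G=5.0, X=0.5, I=7.0),
        reference=ReferenceTrajectory(G0=5.0),
        horizon=30.0,
    )
    with pytest.raises(GuardError):
        simulate(sc)


def test_disabled_fault_and_unit_dropout_do_not_change_nominal_run():
    base = simulate(short(preset("nominal-adaptive"), 180.0))
    decorated = replace(
        preset("nominal-adaptive"),
        horizon=180.0,
        fault=ActuatorFaultProfile(enabled=False),
        dropout=DropoutWindow(attenuation=1.0),
    )
    res = simulate(decorated)
    assert np.array_equal(base.G, res.G)
    assert np.array_equal(base.u_applied, res.u_applied)


def test_fault_then_dropout_composition_order(dropout_adaptive):
    sc = replace(preset("dropout-adaptive"), fault=ActuatorFaultProfile(), horizon=300.0)
    res = simulate(sc)
    inside = (res.t > 240) & (res.t < 300)
    for t, u_cmd, u_app in zip(
        res.t[inside], res.u_commanded[inside], res.u_applied[inside]
    ):
        expected = apply_dropout(apply_actuator_fault(u_cmd, t, sc.fault), t, sc.dropout)
        assert u_app == pytest.approx(expected, rel=1e-12, abs=1e-15)


def test_controller_never_sees_the_fault(faults_adaptive, nominal_adaptive):
    """Faults act between controller and plant: commanded u differs from
    applied u, and D_hat responds only through the glucose error."""
    res = faults_adaptive
    late = res.t > 60
    assert not np.allclose(res.u_commanded[late], res.u_applied[late])


def test_dhat_constant_when_not_adaptive(nominal_backstepping):
    assert np.all(nominal_backstepping.D_hat == 0.0)


def test_refinement_stability(nominal_adaptive):
    """Halving the controller step and tolerances moves the post-lunch peak
    by far less than 1%: the reported numbers are solver-converged."""
    refined = simulate(preset("nominal-adaptive").refined())
    base_peak, _ = peak_in_window(nominal_adaptive, 480, 840)
    fine_peak, _ = peak_in_window(refined, 480, 840)
    assert abs(fine_peak - base_peak) / base_peak < 0.01


def test_lyapunov_series_first_sample(nominal_adaptive):
    """At t=0: e1 = 0 (reference starts at G0), D = D_hat = 0, so V3 is the
    pure e2/e3 start-up term."""
    res = nominal_adaptive
    V = lyapunov_series(res)
    expected = 0.5 * (res.e2[0] ** 2 + res.e3[0] ** 2)
    assert res.e1[0] == 0.0
    assert V[0] == pytest.approx(expected, rel=1e-12)


def test_lyapunov_series_requires_adaptive_mode(nominal_backstepping):
    with pytest.raises(ValueError):
        lyapunov_series(nominal_backstepping)


def test_analytic_derivative_scheme_runs_and_tracks():
    sc = replace(preset("nominal-adaptive"), derivative_scheme="analytic", horizon=600.0)
    res = simulate(sc)
    # Same qualitative behaviour as the hold scheme: tight tracking.
    assert np.max(np.abs(res.G[res.t > 60] - res.G_d[res.t > 60])) < 10.0


def test_invalid_scenarios_rejected():
    with pytest.raises(ValueError):
        Scenario(mode="pid")
    with pytest.raises(ValueError):
        Scenario(controller_step=0.3)  # report grid not a multiple
    with pytest.raises(ValueError):
        Scenario(delta=0.0)
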