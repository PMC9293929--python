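"""Scenario configuration files and result serialisation.

Scenarios are described by a YAML document with sections ``patient``,
``meals``, ``reference``, ``controller``, ``faults``, ``dropout`` and
``simulation``; every omitted key takes the nominal-day default, so an
empty document is the nominal adaptive scenario.  Unknown keys are
rejected with a field-precise message.  A top-level ``preset`` key seeds
the document from a named experiment before the explicit sections are
applied.

Results are written as a CSV time series (one row per report-grid
minute), a JSON scenario echo in the same config schema (so it can be
reloaded and re-run), and a JSON metrics summary.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .backstepping import ControllerGains
from .engine import RESULT_COLUMNS, Scenario, SimulationResult
from .faults import ActuatorFaultProfile, DropoutWindow
from .metrics import summarize
from .model import MealEvent, MealSchedule, PlantState, ReferenceTrajectory
from .scenarios import PRESET_NAMES, preset

__all__ = ["load_scenario", "scenario_from_config", "scenario_to_config", "write_result"]

_PRESET_ALIASES = {"dropout": "dropout-adaptive", "faults": "faults-adaptive"}


class ConfigError(ValueError):
    """A scenario document violates the schema or a physical invariant."""


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {where!r}; "
            f"allowed: {sorted(allowed)}"
        )


def _section(doc: Mapping[str, Any], name: str) -> dict:
    sec = doc.get(name) or {}
    if not isinstance(sec, Mapping):
        raise ConfigError(f"section {name!r} must be a mapping")
    return dict(sec)


def scenario_from_config(doc: Optional[Mapping[str, Any]]) -> Scenario:
    """Build a validated Scenario from a parsed configuration mapping."""
    doc = dict(doc or {})
    _check_keys(
        doc,
        {"preset", "patient", "meals", "reference", "controller", "faults",
         "dropout", "simulation", "label"},
        "<top level>",
    )

    base: Scenario
    if "preset" in doc:
        name = _PRESET_ALIASES.get(doc["preset"], doc["preset"])
        built = preset(name)
        if isinstance(built, list):
            raise ConfigError(f"preset {doc['preset']!r} is a sweep; pick one scenario")
        base = built
    else:
        base = preset("nominal-adaptive")

    try:
        patient = _section(doc, "patient")
        _check_keys(patient, {"p1", "p2", "p3", "n", "Gb", "Ib"}, "patient")
        params = replace(base.params, **{k: float(v) for k, v in patient.items()})

        meals_sec = _section(doc, "meals")
        _check_keys(meals_sec, {"events", "superposition"}, "meals")
        meals = base.meals
        if meals_sec:
            events = meals_sec.get("events")
            if events is None:
                events = list(meals.meals)
            else:
                parsed = []
                for i, ev in enumerate(events):
                    _check_keys(ev, {"t_onset", "A", "B"}, f"meals.events[{i}]")
                    parsed.append(MealEvent(**{k: float(v) for k, v in ev.items()}))
                events = parsed
            meals = MealSchedule(
                events, superposition=meals_sec.get("superposition", meals.superposition)
            )

        sim = _section(doc, "simulation")
        _check_keys(
            sim,
            {"horizon", "initial", "report_step", "rtol", "atol"},
            "simulation",
        )
        initial = base.initial
        if "initial" in sim:
            _check_keys(sim["initial"], {"G", "X", "I"}, "simulation.initial")
            initial = replace(initial, **{k: float(v) for k, v in sim["initial"].items()})

        ref_sec = _section(doc, "reference")
        _check_keys(ref_sec, {"G0", "Ginf", "tau"}, "reference")
        # Reference start follows the initial glucose unless set explicitly.
        ref_defaults = {"G0": initial.G, "Ginf": base.reference.Ginf, "tau": base.reference.tau}
        ref_defaults.update({k: float(v) for k, v in ref_sec.items()})
        reference = ReferenceTrajectory(**ref_defaults)

        ctrl = _section(doc, "controller")
        _check_keys(
            ctrl,
            {"k1", "k2", "k3", "delta", "mode", "step", "derivative_scheme",
             "nonnegative_insulin", "d_hat0"},
            "controller",
        )
        gains = replace(
            base.gains,
            **{k: float(ctrl[k]) for k in ("k1", "k2", "k3") if k in ctrl},
        )

        fault = base.fault
        if "faults" in doc:
            fs = _section(doc, "faults")
            _check_keys(
                fs,
                {"enabled", "rho_floor", "rho_span", "rho_rate", "phi_amp", "phi_rate"},
                "faults",
            )
            fault = ActuatorFaultProfile(**fs) if fs else ActuatorFaultProfile()

        dropout = base.dropout
        if "dropout" in doc:
            ds = _section(doc, "dropout")
            _check_keys(ds, {"t_start", "t_end", "attenuation"}, "dropout")
            dropout = DropoutWindow(**{k: float(v) for k, v in ds.items()})

        return Scenario(
            params=params,
            meals=meals,
            reference=reference,
            gains=gains,
            delta=float(ctrl.get("delta", base.delta)),
            mode=ctrl.get("mode", base.mode),
            fault=fault,
            dropout=dropout,
            initial=initial,
            horizon=float(sim.get("horizon", base.horizon)),
            controller_step=float(ctrl.get("step", base.controller_step)),
            report_step=float(sim.get("report_step", base.report_step)),
            rtol=float(sim.get("rtol", base.rtol)),
            atol=float(sim.get("atol", base.atol)),
            derivative_scheme=ctrl.get("derivative_scheme", base.derivative_scheme),
            nonnegative_insulin=bool(ctrl.get("nonnegative_insulin", base.nonnegative_insulin)),
            d_hat0=float(ctrl.get("d_hat0", base.d_hat0)),
            label=doc.get("label", base.label),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a YAML (or JSON) scenario document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is not None and not isinstance(doc, Mapping):
        raise ConfigError("scenario document must be a mapping (or empty)")
    return scenario_from_config(doc)


def scenario_to_config(sc: Scenario) -> dict:
    """The config-schema echo of a scenario (reloadable by load_scenario)."""
    doc: dict[str, Any] = {
        "label": sc.label,
        "patient": {k: getattr(sc.params, k) for k in ("p1", "p2", "p3", "n", "Gb", "Ib")},
        "meals": {
            "superposition": sc.meals.superposition,
            "events": [
                {"t_onset": m.t_onset, "A": m.A, "B": m.B} for m in sc.meals
            ],
        },
        "reference": {"G0": sc.reference.G0, "Ginf": sc.reference.Ginf, "tau": sc.reference.tau},
        "controller": {
            "k1": sc.gains.k1, "k2": sc.gains.k2, "k3": sc.gains.k3,
            "delta": sc.delta, "mode": sc.mode, "step": sc.controller_step,
            "derivative_scheme": sc.derivative_scheme,
            "nonnegative_insulin": sc.nonnegative_insulin, "d_hat0": sc.d_hat0,
        },
        "simulation": {
            "horizon": sc.horizon,
            "initial": {"G": sc.initial.G, "X": sc.initial.X, "I": sc.initial.I},
            "report_step": sc.report_step, "rtol": sc.rtol, "atol": sc.atol,
        },
    }
    if sc.fault is not None:
        doc["faults"] = {
            k: getattr(sc.fault, k)
            for k in ("enabled", "rho_floor", "rho_span", "rho_rate", "phi_amp", "phi_rate")
        }
    if sc.dropout is not None:
        doc["dropout"] = {
            k: getattr(sc.dropout, k) for k in ("t_start", "t_end", "attenuation")
        }
    return doc


def write_result(result: SimulationResult, out_dir: str | Path, stem: Optional[str] = None) -> dict:
    """Write the CSV series plus JSON scenario echo and metrics summary.

    Returns a mapping from artefact kind to the written path.  Byte
    content is deterministic for a fixed scenario.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or result.scenario.label or "run"

    csv_path = out / f"{stem}_timeseries.csv"
    frame = result.to_frame()[list(RESULT_COLUMNS)]
    frame.to_csv(csv_path, index=False, lineterminator="\n")

    scen_path = out / f"{stem}_scenario.json"
    with open(scen_path, "w") as fh:
        json.dump(scenario_to_config(result.scenario), fh, indent=2, sort_keys=True)
        fh.write("\n")

    metrics_path = out / f"{stem}_metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump(summarize(result), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"timeseries": csv_path, "scenario": scen_path, "metrics": metrics_path}
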