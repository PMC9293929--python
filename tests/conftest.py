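"""Shared closed-loop runs (session-scoped: each full-day run costs ~1 s)."""

import pytest

from glucostep import nominal_scenario, preset, simulate


@pytest.fixture(scope="session")
def nominal_adaptive():
    return simulate(preset("nominal-adaptive"))


@pytest.fixture(scope="session")
def nominal_backstepping():
    return simulate(preset("nominal-backstepping"))


@pytest.fixture(scope="session")
def untreated():
    return simulate(preset("untreated"))


@pytest.fixture(scope="session")
def faults_adaptive():
    return simulate(preset("faults-adaptive"))


@pytest.fixture(scope="session")
def faults_backstepping():
    return simulate(preset("faults-backstepping"))


@pytest.fixture(scope="session")
def dropout_adaptive():
    return simulate(preset("dropout-adaptive"))


@pytest.fixture(scope="session")
def dropout_backstepping():
    return simulate(preset("dropout-backstepping"))


@pytest.fixture(scope="session")
def harsh_start_adaptive():
    """Adaptive loop from the harshest fasting level, G0 = 320 mg/dl."""
    return simulate(nominal_scenario("adaptive", G0=320.0))
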