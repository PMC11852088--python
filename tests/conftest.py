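"""Shared fixtures: the expensive artifacts (synergy set, OFC solutions,
scenario rollouts) are computed once per session and reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from neuroarm.arm import default_arm
from neuroarm.engine import ScenarioConfig, run_center_out, simulate_scenario
from neuroarm.ofc import InternalModelParams
from neuroarm.synergies import learn_synergies


@pytest.fixture(scope="session")
def arm():
    return default_arm()


@pytest.fixture(scope="session")
def synergies(arm):
    return learn_synergies(arm, seed=0)


@pytest.fixture(scope="session")
def params():
    return InternalModelParams()


@pytest.fixture(scope="session")
def center_out_runs(arm, synergies):
    """Noise-free center-out reaches for b = 0, +3, -3 N s/m."""
    runs = {}
    for b in (0.0, 3.0, -3.0):
        cfg = ScenarioConfig(scenario="curl" if b else "center_out", field_b=b)
        runs[b] = run_center_out(cfg, arm=arm, synergies=synergies)
    return runs


@pytest.fixture(scope="session")
def scenario_runs(arm, synergies):
    """Noise-free interaction scenarios A, B, D (C is exercised separately)."""
    from neuroarm.control import reference_from_result

    out = {}
    out["A"] = simulate_scenario(ScenarioConfig(scenario="A"),
                                 arm=arm, synergies=synergies)
    out["B"] = simulate_scenario(ScenarioConfig(scenario="B"),
                                 arm=arm, synergies=synergies)
    out["D"] = simulate_scenario(
        ScenarioConfig(scenario="D", reference=reference_from_result(out["A"])),
        arm=arm, synergies=synergies)
    return out


@pytest.fixture(scope="session")
def scenario_c_run(arm, synergies):
    """Scenario C (human-aware control) at the full 221-step horizon."""
    return simulate_scenario(ScenarioConfig(scenario="C"),
                             arm=arm, synergies=synergies)


@pytest.fixture(scope="session")
def scaled_scenario_runs(arm, synergies):
    """Scenarios A, B, C at a shortened horizon (N = 121: 0.5 s transport
    plus the 21-step dwell) so the predictive-control loop stays affordable."""
    p = InternalModelParams(n_steps=121)
    out = {}
    for name in ("A", "B", "C"):
        out[name] = simulate_scenario(
            ScenarioConfig(scenario=name, params=p), arm=arm, synergies=synergies)
    return out
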