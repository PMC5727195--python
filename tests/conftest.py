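"""Shared fixtures: the synthetic gait trial, its recruitment solutions and
the solved toy-knee states are expensive, so they are session-scoped."""

import warnings

import numpy as np
import pytest

from kneemech import fdk, fixtures
from kneemech.pipeline import solve_gait_recruitment

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def gait_trial():
    return fixtures.generate_gait_record()


@pytest.fixture(scope="session")
def gait_results(gait_trial):
    return solve_gait_recruitment(gait_trial)


@pytest.fixture(scope="session")
def toy_knee():
    """Symmetric toy knee with patella plus its solved FDK states."""
    fix = fixtures.generate_fixture_knee(symmetric_ligaments=True, with_patella=True)
    knee = fixtures.toy_knee_assembly(fix, quadriceps_force=400.0)
    axial = np.array([0.0, -800.0, 0.0, 0.0, 0.0, 0.0])
    state_axial = fdk.solve_fdk_frame(knee, 0.0, axial)
    valgus = np.array([0.0, -800.0, 0.0, 0.0, 0.0, 25.0])
    state_valgus = fdk.solve_fdk_frame(knee, 0.0, valgus, state0=state_axial)
    return {"knee": knee, "fixture": fix, "axial_load": axial,
            "state_axial": state_axial, "valgus_load": valgus,
            "state_valgus": state_valgus}


@pytest.fixture(scope="session")
def tf_only_knee():
    """Tibiofemoral-only symmetric toy knee and its axially loaded state."""
    fix = fixtures.generate_fixture_knee(symmetric_ligaments=True)
    knee = fixtures.toy_knee_assembly(fix)
    axial = np.array([0.0, -800.0, 0.0, 0.0, 0.0, 0.0])
    state = fdk.solve_fdk_frame(knee, 0.0, axial)
    return {"knee": knee, "axial_load": axial, "state": state}
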