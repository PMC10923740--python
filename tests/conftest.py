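"""Shared fixtures: one default phantom and its fully executed virtual HTO.

The heavier pipeline artifacts are session-scoped so the many tests that
probe the same default specimen do not regenerate it.
"""

import numpy as np
import pytest
import trimesh

from hto3d import (
    ErrorModel,
    SyntheticTibiaParams,
    anatomical_axis,
    build_frame,
    execute_hto,
    generate_tibia,
    measure_angles,
    plan_hto,
    simulate_surgical_error,
)

#: Coarser discretization used where many specimens are generated; the
#: angle-recovery error it introduces is < 0.01 deg (see docs/methods.md).
COARSE = (24, 100)


@pytest.fixture(scope="session")
def default_specimen():
    mesh, landmarks, truth = generate_tibia()
    return mesh, landmarks, truth


@pytest.fixture(scope="session")
def default_frame(default_specimen):
    _, landmarks, _ = default_specimen
    return build_frame(landmarks)


@pytest.fixture(scope="session")
def default_axis(default_specimen, default_frame):
    mesh, _, _ = default_specimen
    return anatomical_axis(mesh, default_frame)


@pytest.fixture(scope="session")
def default_plan(default_specimen, default_frame, default_axis):
    mesh, landmarks, _ = default_specimen
    return plan_hto(mesh, landmarks, default_frame, default_axis, gap_target=8.0)


@pytest.fixture(scope="session")
def default_result(default_specimen, default_plan):
    mesh, landmarks, _ = default_specimen
    return execute_hto(mesh, landmarks, default_plan)


@pytest.fixture(scope="session")
def planned_state(default_result):
    """Ideal post-osteotomy bone and its angles (the '3D plan')."""
    planned_mesh = trimesh.util.concatenate(
        [default_result.proximal_fragment, default_result.distal_fragment])
    angles = measure_angles(planned_mesh, default_result.realized_landmarks)
    return planned_mesh, default_result.realized_landmarks, angles


@pytest.fixture(scope="session")
def ideal_execution(default_result):
    """Realized bone under an identity error model (perfect surgery)."""
    return simulate_surgical_error(default_result, ErrorModel())


@pytest.fixture(scope="session")
def coarse_specimen():
    mesh, landmarks, truth = generate_tibia(SyntheticTibiaParams(mesh_resolution=COARSE))
    return mesh, landmarks, truth


def random_rigid(rng):
    """A reproducible random rigid transform with a nontrivial rotation."""
    from scipy.spatial.transform import Rotation

    from hto3d import RigidTransform

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return RigidTransform(R, t)
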