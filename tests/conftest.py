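"""Shared fixtures: synthetic femurs are expensive enough to build once."""

import numpy as np
import pytest
import trimesh

from femcurve import FemurParams, make_femur_meshes


@pytest.fixture(scope="session")
def default_params():
    return FemurParams()


@pytest.fixture(scope="session")
def default_femur(default_params):
    """(cortex, canal, truth) for the default left femur."""
    return make_femur_meshes(default_params)


@pytest.fixture(scope="session")
def bowed_femur():
    """A femur with an off-axis bow (banking != 90, offset apex)."""
    params = FemurParams(
        R_curvature=900.0, banking=105.0, apex_offset=0.15, isthmus_frac=0.6
    )
    return params, make_femur_meshes(params)


@pytest.fixture(scope="session")
def cylinder_mesh():
    return trimesh.creation.cylinder(radius=5.0, height=100.0, sections=64)


def random_rigid_transform(rng):
    """A uniformly random proper rigid motion (helper, not a fixture)."""
    from femcurve import RigidTransform

    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return RigidTransform(q, rng.uniform(-100.0, 100.0, 3))
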