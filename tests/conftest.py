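import numpy as np
import pytest

import resdisc as rd
from resdisc.geometry import Mesh, assign_region_params


@pytest.fixture(scope="session")
def table():
    return rd.default_material_table()


@pytest.fixture(scope="session")
def env():
    return rd.default_environment()


def unit_hex_mesh(region="NP"):
    """Single unit-cube hexahedron with the given region label."""
    nodes = np.array(
        [
            [0, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [1, 0, 1],
            [1, 1, 1],
            [0, 1, 1],
        ],
        dtype=float,
    )
    elems = np.array([[0, 1, 2, 3, 4, 5, 6, 7]])
    mesh = Mesh(
        nodes=nodes,
        elems=elems,
        region=np.array([region]),
        node_sets={
            "superior": np.array([4, 5, 6, 7]),
            "inferior": np.array([0, 1, 2, 3]),
        },
        cut_pairs=np.zeros((0, 2), dtype=np.int64),
    )
    assign_region_params(mesh, rd.default_material_table())
    return mesh


@pytest.fixture()
def np_hex():
    return unit_hex_mesh("NP")


@pytest.fixture()
def oaf_hex():
    return unit_hex_mesh("OAF")


@pytest.fixture(scope="session")
def coarse_bovine_spec():
    """Small bovine cylinder for fast protocol tests."""
    return rd.GeometrySpec(
        shape="bovine_cylinder", n_theta=16, n_axial=2, n_np=1, n_iaf=2, n_oaf=2
    )


def admissible_deformations(n, rng, max_strain=0.25):
    """Random deformation gradients with positive J, moderate strain."""
    out = []
    while len(out) < n:
        F = np.eye(3) + max_strain * (rng.random((3, 3)) - 0.5)
        if np.linalg.det(F) > 0.3:
            out.append(F)
    return np.array(out)
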