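"""Finite-element core: trivial equilibria, single-element consistency with
the material point, patch uniformity, work-energy balance, determinism."""

import numpy as np
import pytest
from scipy.optimize import brentq

import resdisc as rd
from resdisc.fem import FESystem, newton_solve, ramp
from resdisc.geometry import Mesh, assign_region_params
from resdisc.materials import DeformationState

from conftest import unit_hex_mesh


def two_hex_mesh(region="NP"):
    nodes = []
    for z in (0.0, 1.0):
        for y in (0.0, 1.0):
            for x in (0.0, 1.0, 2.0):
                nodes.append((x, y, z))
    nodes = np.asarray(nodes, dtype=float)

    def nid(ix, iy, iz):
        return iz * 6 + iy * 3 + ix

    elems = []
    for ix in range(2):
        elems.append(
            [
                nid(ix, 0, 0),
                nid(ix + 1, 0, 0),
                nid(ix + 1, 1, 0),
                nid(ix, 1, 0),
                nid(ix, 0, 1),
                nid(ix + 1, 0, 1),
                nid(ix + 1, 1, 1),
                nid(ix, 1, 1),
            ]
        )
    mesh = Mesh(
        nodes=nodes,
        elems=np.asarray(elems),
        region=np.array([region, region]),
        node_sets={
            "superior": np.array([nid(i, j, 1) for j in range(2) for i in range(3)]),
            "inferior": np.array([nid(i, j, 0) for j in range(2) for i in range(3)]),
        },
        cut_pairs=np.zeros((0, 2), dtype=np.int64),
    )
    assign_region_params(mesh, rd.default_material_table())
    return mesh


def test_zero_load_zero_displacement(np_hex):
    sys = FESystem(np_hex)
    sys.set_prescribed(np.array([0, 1, 2, 3]), (0, 1, 2), 0.0)
    info = newton_solve(sys)
    assert info["residual"] < 1e-12
    assert np.allclose(sys.u, 0.0)


def test_single_element_confined_compression_matches_material_point(np_hex, table):
    """Prescribed axial stretch with confined lateral faces: the reaction
    stress must equal the Holmes--Mow law evaluated at diag(1,1,lambda)."""
    sys = FESystem(np_hex)
    lam_z = 0.9
    allnodes = np.arange(8)
    sys.set_prescribed(allnodes, (0, 1), 0.0)
    sys.set_prescribed(np.array([0, 1, 2, 3]), (2,), 0.0)
    sys.set_prescribed(np.array([4, 5, 6, 7]), (2,), lam_z - 1.0)
    newton_solve(sys)
    F = np.diag([1.0, 1.0, lam_z])
    sig_exact = rd.holmes_mow_stress(DeformationState(F=F), table["NP"])[2, 2]
    # reaction force on the top face = Cauchy stress * current area (1 x 1)
    fz = sys.reaction(np.array([4, 5, 6, 7]))[:, 2].sum()
    assert fz == pytest.approx(sig_exact, rel=1e-8)


def eight_hex_patch(region="NP"):
    """2x2x2 patch of unit hexes: one true interior node."""
    xs = np.array([0.0, 1.0, 2.0])
    nodes = np.array([(x, y, z) for z in xs for y in xs for x in xs])

    def nid(ix, iy, iz):
        return iz * 9 + iy * 3 + ix

    elems = []
    for iz in range(2):
        for iy in range(2):
            for ix in range(2):
                elems.append(
                    [
                        nid(ix, iy, iz),
                        nid(ix + 1, iy, iz),
                        nid(ix + 1, iy + 1, iz),
                        nid(ix, iy + 1, iz),
                        nid(ix, iy, iz + 1),
                        nid(ix + 1, iy, iz + 1),
                        nid(ix + 1, iy + 1, iz + 1),
                        nid(ix, iy + 1, iz + 1),
                    ]
                )
    mesh = Mesh(
        nodes=nodes,
        elems=np.asarray(elems),
        region=np.array([region] * 8),
        node_sets={"superior": np.array([]), "inferior": np.array([])},
        cut_pairs=np.zeros((0, 2), dtype=np.int64),
    )
    assign_region_params(mesh, rd.default_material_table())
    return mesh


def test_patch_uniform_stress(table):
    """Affine displacement on the patch boundary: the interior node must land
    on the affine map and the deformation (hence stress) field be uniform."""
    mesh = eight_hex_patch()
    sys = FESystem(mesh)
    F = np.array([[1.04, 0.02, 0.0], [0.0, 0.97, 0.01], [0.0, 0.0, 1.02]])
    u_aff = mesh.nodes @ (F - np.eye(3)).T
    interior = 13  # center node of the 3x3x3 grid
    ext = np.array([n for n in range(mesh.n_nodes) if n != interior])
    sys.set_prescribed(ext, (0, 1, 2), u_aff[ext])
    newton_solve(sys)
    assert np.allclose(sys.u[interior], u_aff[interior], atol=1e-8)
    Fg, _ = sys.deformation_gradients(sys.u[mesh.elems])
    assert np.allclose(Fg, F, atol=1e-8)
    sig = rd.holmes_mow_stress(DeformationState(F=F), table["NP"])
    P = sys.piola(Fg, np.linalg.det(Fg))
    sig_fe = P @ np.swapaxes(Fg, -1, -2) / np.linalg.det(Fg)[..., None, None]
    assert np.allclose(sig_fe, sig, atol=1e-8)


def test_single_element_confined_swelling_matches_root_find(np_hex, table, env):
    """FE Donnan-equilibrated swelling of a confined element against the
    closed-form axial stress balance solved by brentq."""
    sys = FESystem(np_hex)
    allnodes = np.arange(8)
    sys.set_prescribed(allnodes, (0, 1), 0.0)
    sys.set_prescribed(np.array([0, 1, 2, 3]), (2,), 0.0)
    ramp(sys, lambda s: setattr(sys, "alpha", s), n_sub=10)
    lam_fe = 1.0 + sys.u[4:, 2].mean()
    p = table["NP"]

    def balance(lam):
        st = DeformationState(F=np.diag([1.0, 1.0, lam]))
        sig = rd.holmes_mow_stress(st, p)[2, 2]
        pi = rd.donnan_pressure(rd.fixed_charge_density(lam, p), env)
        return sig - pi

    lam_oracle = brentq(balance, 1.0, 3.0, xtol=1e-14)
    assert lam_fe == pytest.approx(lam_oracle, rel=1e-6)


def test_work_energy_balance_single_element(oaf_hex):
    """External work along a drained quasi-static stretch path equals the
    stored strain energy within 1% (elastic path, no swelling)."""
    sys = FESystem(oaf_hex)
    allnodes = np.arange(8)
    top = np.array([4, 5, 6, 7])
    sys.set_prescribed(allnodes, (0, 1), 0.0)
    sys.set_prescribed(np.array([0, 1, 2, 3]), (2,), 0.0)
    target = 0.08
    n_steps = 40
    work = 0.0
    f_prev = 0.0
    for k in range(1, n_steps + 1):
        dz = k * target / n_steps
        sys.set_prescribed(top, (2,), dz)
        newton_solve(sys)
        f = sys.reaction(top)[:, 2].sum()
        work += 0.5 * (f + f_prev) * (target / n_steps)
        f_prev = f
    stored = sys.strain_energy()
    assert work == pytest.approx(stored, rel=0.01)


def test_fbar_uniform_state_unchanged(np_hex):
    """For a spatially uniform deformation the mean-dilatation treatment is
    the identity."""
    sys = FESystem(np_hex)
    u = np_hex.nodes @ (np.diag([1.1, 0.9, 1.05]) - np.eye(3)).T
    F1, J1 = sys.deformation_gradients(u[np_hex.elems], fbar=True)
    F2, J2 = sys.deformation_gradients(u[np_hex.elems], fbar=False)
    assert np.allclose(F1, F2, atol=1e-12)
    assert np.allclose(J1, J2, atol=1e-12)


def test_solver_determinism(coarse_bovine_spec):
    """Identical configurations produce bit-identical results."""

    def run():
        mesh = rd.build_bovine_cylinder(coarse_bovine_spec)
        rd.assign_region_params(mesh, rd.default_material_table())
        from resdisc.protocols import DiscSimulation

        sim = DiscSimulation(mesh, mode="swelling_only")
        sim.swell(n_sub=4)
        return sim.sys.u.copy()

    u1, u2 = run(), run()
    assert np.array_equal(u1, u2)
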