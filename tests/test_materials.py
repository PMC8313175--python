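"""Constitutive-law unit tests: worked examples frozen from independent
oracles (symbolic/scalar computation), stress-energy consistency, objectivity,
and monotonicity properties."""

import numpy as np
import pytest

import resdisc as rd
from resdisc.materials import (
    DeformationState,
    InvalidParameterError,
    InvertedElementError,
    MaterialParams,
)

from conftest import admissible_deformations

RNG = np.random.default_rng(20240317)


def rot_matrix(rng):
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# ---------------------------------------------------------------- parameters


def test_lame_from_engineering_examples():
    assert rd.lame_from_engineering(1.0, 0.0) == (0.0, 0.5)
    lam, mu = rd.lame_from_engineering(0.065, 0.24)
    assert lam == pytest.approx(0.02419, rel=1e-3)
    assert mu == pytest.approx(0.02621, rel=1e-3)
    lam, mu = rd.lame_from_engineering(0.018, 0.24)
    assert lam == pytest.approx(0.00670, rel=1e-3)
    assert mu == pytest.approx(0.00726, rel=1e-3)


@pytest.mark.parametrize("nu", [0.5, -1.0, 0.7])
def test_lame_rejects_limit_poisson(nu):
    with pytest.raises(InvalidParameterError):
        rd.lame_from_engineering(1.0, nu)


def test_material_params_invariants(table):
    with pytest.raises(InvalidParameterError):
        MaterialParams(region_label="NP", E_m=-1, nu=0.2, beta_m=1, k0=1, M=1, c0F=0)
    with pytest.raises(InvalidParameterError):
        MaterialParams(
            region_label="OAF", E_m=1, nu=0.2, beta_m=1, k0=1, M=1, c0F=0,
            E_f=1.0, lambda0=0.9, theta=30.0, beta_f=4.0,
        )
    p = table["OAF"]
    assert p.phi0_s + p.phi0_w == pytest.approx(1.0)


# ------------------------------------------------------------- matrix laws


def test_holmes_mow_zero_stress_at_reference(table):
    st = DeformationState(F=np.eye(3))
    sig = rd.holmes_mow_stress(st, table["NP"])
    assert np.allclose(sig, 0.0, atol=1e-14)
    assert np.isfinite(rd.holmes_mow_energy(st, table["NP"]))


def test_holmes_mow_energy_frozen_value(table):
    # diag(1.05, 1, 1), NP row; expected from an independent symbolic
    # evaluation of the energy (sympy, exact rationals)
    st = DeformationState(F=np.diag([1.05, 1.0, 1.0]))
    W = rd.holmes_mow_energy(st, table["NP"])
    assert W == pytest.approx(9.444812082552344e-05, rel=1e-10)


def test_inverted_element_raises(table):
    with pytest.raises(InvertedElementError):
        DeformationState(F=np.diag([-1.0, 1.0, 1.0]))


@pytest.mark.parametrize("region", ["NP", "OAF", "CEP"])
def test_holmes_mow_objectivity(table, region):
    F = np.diag([1.07, 0.95, 1.01]) + 0.03 * RNG.standard_normal((3, 3))
    p = table[region]
    W0 = rd.holmes_mow_energy(DeformationState(F=F), p)
    for _ in range(5):
        R = rot_matrix(RNG)
        st = DeformationState(F=R @ F)
        assert rd.holmes_mow_energy(st, p) == pytest.approx(W0, rel=1e-12)
        sig = rd.holmes_mow_stress(st, p)
        sig0 = rd.holmes_mow_stress(DeformationState(F=F), p)
        assert np.allclose(sig, R @ sig0 @ R.T, atol=1e-10)


def _fd_stress(energy, F, h=1e-6):
    """Cauchy stress from central finite differences of an energy W(F):
    sigma = J^-1 dW/dF F^T."""
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (energy(Fp) - energy(Fm)) / (2 * h)
    return P @ F.T / np.linalg.det(F)


@pytest.mark.parametrize("region", ["NP", "OAF", "IAF", "CEP"])
def test_stress_energy_consistency_holmes_mow(table, region):
    p = table[region]
    for F in admissible_deformations(10, RNG):
        sig = rd.holmes_mow_stress(DeformationState(F=F), p)
        fd = _fd_stress(lambda G: rd.holmes_mow_energy(DeformationState(F=G), p), F)
        assert np.allclose(sig, fd, rtol=1e-5, atol=1e-9)
        assert np.allclose(sig, sig.T, atol=1e-12)


def test_neo_hookean_zero_at_identity_and_linearization():
    st = DeformationState(F=np.eye(3))
    assert np.allclose(rd.neo_hookean_stress(st, 10000.0, 0.3), 0.0)
    # small-strain limit matches linear elasticity
    eps = 1e-6
    F = np.eye(3)
    F[0, 0] += eps
    sig = rd.neo_hookean_stress(DeformationState(F=F), 10000.0, 0.3)
    lam, mu = rd.lame_from_engineering(10000.0, 0.3)
    lin = lam * eps * np.eye(3)
    lin[0, 0] += 2 * mu * eps
    assert np.allclose(sig, lin, rtol=1e-3)


def test_neo_hookean_stress_energy_consistency():
    F = np.diag([1.01, 1.0, 1.0])
    sig = rd.neo_hookean_stress(DeformationState(F=F), 10000.0, 0.3)
    fd = _fd_stress(
        lambda G: rd.materials.neo_hookean_energy(DeformationState(F=G), 10000.0, 0.3),
        F,
        h=1e-5,
    )
    assert np.allclose(sig, fd, rtol=1e-5)


# ----------------------------------------------------- transport & swelling


def test_permeability_reference_and_example(table):
    p = table["OAF"]
    assert rd.permeability(1.0, p) == pytest.approx(p.k0, rel=1e-14)
    assert rd.permeability(1.2, p) == pytest.approx(0.0275, rel=2e-3)
    assert rd.permeability(0.9, p) < p.k0
    J = np.linspace(0.5, 1.6, 40)
    k = rd.permeability(J, p)
    assert np.all(np.diff(k) > 0)
    with pytest.raises(InvalidParameterError):
        rd.permeability(p.phi0_s, p)


def test_fixed_charge_density_dilution(table):
    p = table["NP"]
    assert rd.fixed_charge_density(1.0, p) == pytest.approx(p.c0F)
    assert rd.fixed_charge_density(2.0, p) == pytest.approx(
        p.phi0_w / (1.0 + p.phi0_w) * 379.0
    )
    # spec-sheet worked value with phi0_w = 0.8
    p8 = MaterialParams(
        region_label="NP", E_m=0.065, nu=0.24, beta_m=0.95, k0=5.6e-4, M=3.79,
        c0F=379.0, phi0_s=0.2,
    )
    assert rd.fixed_charge_density(2.0, p8) == pytest.approx(168.44, rel=1e-3)
    J = np.linspace(0.9, 5.0, 50)
    c = rd.fixed_charge_density(J, p)
    assert np.all(np.diff(c) < 0)
    assert rd.fixed_charge_density(1e9, p) < 1e-5


def test_donnan_pressure(env):
    assert rd.donnan_pressure(0.0, env) == 0.0
    env0 = rd.Environment(bath_osmolarity=0.0)
    cF = 123.0
    assert rd.donnan_pressure(cF, env0) == pytest.approx(env0.RT_mpa * cF, rel=1e-14)
    assert rd.donnan_pressure(379.0, env) == pytest.approx(0.47, abs=0.005)
    c = np.linspace(0.0, 500.0, 60)
    pi = rd.donnan_pressure(c, env)
    assert np.all(np.diff(pi) > 0) and np.all(pi >= 0)
    with pytest.raises(InvalidParameterError):
        rd.donnan_pressure(-1.0, env)


# ------------------------------------------------------------------- fibers


def test_fiber_energy_branches(table):
    p = table["OAF"]
    assert rd.fiber_energy(0.95, p) == 0.0
    # continuity at both branch points
    lam0 = p.lambda0
    below = rd.fiber_energy(lam0 - 1e-9, p)
    above = rd.fiber_energy(lam0 + 1e-9, p)
    assert above == pytest.approx(below, rel=1e-6)
    psi0 = p.E_f * (lam0**2 - 1.0) ** 2 / (4 * p.beta_f * (p.beta_f - 1.0))
    assert rd.fiber_energy(lam0, p) == pytest.approx(psi0, rel=1e-12)
    # frozen toe value at lambda = 1.02 from the symbolic oracle
    assert rd.fiber_energy(1.02, p) == pytest.approx(2.685077698201113e-4, rel=1e-10)


def test_fiber_stress_matches_energy_derivative(table):
    p = table["OAF"]
    assert rd.fiber_stress_1d(0.95, p) == 0.0
    assert rd.fiber_stress_1d(1.0, p) == 0.0
    # frozen toe value (symbolic oracle) and derivative consistency
    assert rd.fiber_stress_1d(1.02, p) == pytest.approx(0.05423325251812149, rel=1e-10)
    h = 1e-7
    for lam in (1.01, 1.02, 1.05, 1.2):
        fd = (rd.fiber_energy(lam + h, p) - rd.fiber_energy(lam - h, p)) / (2 * h)
        assert rd.fiber_stress_1d(lam, p) == pytest.approx(fd, rel=1e-5)
    # C0 at the transition stretch; nondecreasing above engagement
    lam0 = p.lambda0
    assert rd.fiber_stress_1d(lam0 + 1e-9, p) == pytest.approx(
        rd.fiber_stress_1d(lam0 - 1e-9, p), rel=1e-5
    )
    lams = np.linspace(1.0, 1.5, 200)
    s = rd.fiber_stress_1d(lams, p)
    assert np.all(np.diff(s) >= -1e-12)


def test_fiber_free_region_raises(table):
    with pytest.raises(InvalidParameterError):
        rd.fiber_energy(1.1, table["NP"])


# ------------------------------------------------------------- total stress


def test_total_stress_reference_states(table, env):
    st = DeformationState(F=np.eye(3))
    p_oaf = table["OAF"]
    # no swelling activation, slack fibers -> zero
    sig = rd.total_cauchy_stress(
        st, [(0.95, np.array([1.0, 0, 0]))], p_oaf, env, swelling_activation=0.0
    )
    assert np.allclose(sig, 0.0, atol=1e-14)
    # swelling on at reference: isotropic compression -pi(c0F) I
    sig = rd.total_cauchy_stress(st, [], table["NP"], env)
    pi = rd.donnan_pressure(table["NP"].c0F, env)
    assert np.allclose(sig, -pi * np.eye(3), atol=1e-12)


def test_total_stress_constituent_sum(table, env):
    # uniaxial stretch along a fiber: matrix + rank-one fiber + Donnan,
    # each evaluated separately as the oracle
    p = table["OAF"]
    lam_s = 1.05
    F = np.diag([lam_s, 1.0, 1.0])
    st = DeformationState(F=F)
    m = np.array([1.0, 0, 0])
    sig = rd.total_cauchy_stress(st, [(lam_s, m)], p, env)
    expected = rd.holmes_mow_stress(st, p).copy()
    expected += (
        lam_s * rd.fiber_stress_1d(lam_s, p) / st.J * np.outer(m, m)
    )
    expected -= rd.donnan_pressure(rd.fixed_charge_density(st.J, p), env) * np.eye(3)
    assert np.allclose(sig, expected, atol=1e-12)
    assert np.allclose(sig, sig.T)
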