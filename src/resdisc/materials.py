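"""Constitutive relations for disc tissues.

All laws are pure functions of deformation/composition state, vectorized over
leading batch axes: a deformation gradient argument may be shaped ``(3, 3)`` or
``(..., 3, 3)`` and scalar arguments broadcast accordingly.

The solid matrix of every region is a compressible Holmes--Mow hyperelastic
solid.  Swelling enters as a Donnan osmotic pressure acting as an isotropic
Cauchy stress ``-pi * I``, with the fixed charge density diluting as the tissue
swells.  Annulus regions additionally carry two fiber families (+theta and
-theta from the local circumferential direction) with a toe-region power-law /
linear strain-energy density that resists stretch only (buckled fibers are
stress-free).  Hydraulic permeability is strain dependent (Holmes--Mow form)
and is used by the transient consolidation engine; all organ-scale solves in
this package are drained equilibria where permeability drops out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .units import BODY_TEMPERATURE_K, GAS_CONSTANT, PA_TO_MPA

__all__ = [
    "MaterialParams",
    "DeformationState",
    "Environment",
    "InvalidParameterError",
    "InvertedElementError",
    "lame_from_engineering",
    "holmes_mow_energy",
    "holmes_mow_stress",
    "neo_hookean_energy",
    "neo_hookean_stress",
    "permeability",
    "fixed_charge_density",
    "donnan_pressure",
    "fiber_energy",
    "fiber_stress_1d",
    "total_cauchy_stress",
]


class InvalidParameterError(ValueError):
    """A material parameter or input violates its admissible range."""


class InvertedElementError(ValueError):
    """Deformation gradient with non-positive Jacobian."""


REGION_LABELS = ("OAF", "AFtrans", "IAF", "NPtrans", "NP", "CEP", "VB")


@dataclass(frozen=True)
class MaterialParams:
    """Per-region constitutive constants.

    Moduli in MPa, permeability in mm^4/(N s), fixed charge density in mM,
    fiber angle in degrees.  ``E_f`` is ``None`` for fiber-free regions
    (NP, CEP, VB).  ``phi0_s`` is the reference solid volume fraction; the
    reference water fraction is ``1 - phi0_s``.
    """

    region_label: str
    E_m: float
    nu: float
    beta_m: float
    k0: float
    M: float
    c0F: float
    E_f: Optional[float] = None
    lambda0: Optional[float] = None
    theta: Optional[float] = None
    beta_f: Optional[float] = None
    phi0_s: float = 0.3

    def __post_init__(self) -> None:
        if self.region_label not in REGION_LABELS:
            raise InvalidParameterError(f"unknown region label {self.region_label!r}")
        if not self.E_m > 0:
            raise InvalidParameterError("E_m must be positive")
        if not (-1.0 < self.nu < 0.5):
            raise InvalidParameterError("nu must lie strictly in (-1, 0.5)")
        if self.beta_m < 0:
            raise InvalidParameterError("beta_m must be >= 0")
        if not self.k0 > 0:
            raise InvalidParameterError("k0 must be positive")
        if self.c0F < 0:
            raise InvalidParameterError("c0F must be >= 0")
        if not (0.0 < self.phi0_s < 1.0):
            raise InvalidParameterError("phi0_s must lie in (0, 1)")
        if self.has_fibers:
            if not (self.E_f > 0):
                raise InvalidParameterError("E_f must be positive")
            if not (self.lambda0 is not None and self.lambda0 > 1):
                raise InvalidParameterError("lambda0 must exceed 1")
            if not (self.beta_f is not None and self.beta_f > 1):
                raise InvalidParameterError("beta_f must exceed 1")
            if not (self.theta is not None and 0 < self.theta < 90):
                raise InvalidParameterError("theta must lie in (0, 90) degrees")

    @property
    def has_fibers(self) -> bool:
        return self.E_f is not None

    @property
    def phi0_w(self) -> float:
        return 1.0 - self.phi0_s

    @property
    def lame(self) -> tuple[float, float]:
        return lame_from_engineering(self.E_m, self.nu)


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient with cached invariants of C = F^T F."""

    F: np.ndarray
    J: float = field(init=False)
    I1: float = field(init=False)
    I2: float = field(init=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape[-2:] != (3, 3):
            raise InvalidParameterError("F must be a 3x3 tensor (or batch thereof)")
        object.__setattr__(self, "F", F)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise InvertedElementError("det(F) must be positive")
        C = np.swapaxes(F, -1, -2) @ F
        I1 = np.trace(C, axis1=-2, axis2=-1)
        trC2 = np.trace(C @ C, axis1=-2, axis2=-1)
        I2 = 0.5 * (I1 * I1 - trC2)
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "I1", I1)
        object.__setattr__(self, "I2", I2)


@dataclass(frozen=True)
class Environment:
    """External bath and thermodynamic constants for Donnan swelling.

    ``bath_osmolarity`` is the total external osmolarity c* in mOsm/L (mM);
    ``osmotic_coefficient`` is the ideal-Donnan Phi (default 1)."""

    bath_osmolarity: float = 300.0
    temperature: float = BODY_TEMPERATURE_K
    osmotic_coefficient: float = 1.0
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.bath_osmolarity < 0:
            raise InvalidParameterError("bath osmolarity must be >= 0")
        if not self.temperature > 0:
            raise InvalidParameterError("temperature must be positive")
        if not (0 < self.osmotic_coefficient <= 1):
            raise InvalidParameterError("osmotic coefficient must lie in (0, 1]")

    @property
    def RT_mpa(self) -> float:
        """R*T*Phi in MPa per mM of osmotically active species."""
        return (
            self.gas_constant * self.temperature * self.osmotic_coefficient * PA_TO_MPA
        )


def lame_from_engineering(E_m: float, nu: float):
    """Lame parameters (lambda, mu) from Young's modulus and Poisson's ratio."""
    E_m = np.asarray(E_m, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(E_m <= 0):
        raise InvalidParameterError("E_m must be positive")
    if np.any(nu <= -1.0) or np.any(nu >= 0.5):
        raise InvalidParameterError("nu must lie strictly in (-1, 0.5)")
    lam = E_m * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E_m / (2.0 * (1.0 + nu))
    return lam, mu


def _hm_exponent(I1, I2, J, lam, mu, beta):
    """Exponent Q of the Holmes--Mow energy."""
    num = (2.0 * mu - lam) * (I1 - 3.0) + lam * (I2 - 3.0)
    return beta * (num / (lam + 2.0 * mu)) - 2.0 * beta * np.log(J)


def holmes_mow_energy(state: DeformationState, params: MaterialParams):
    """Holmes--Mow strain-energy density W(I1, I2, J) in MPa.

    ``W = (lam + 2 mu)/(4 beta_m) * (exp(Q) - 1)`` with
    ``Q = beta_m * [(2 mu - lam)(I1-3) + lam (I2-3) - (lam+2 mu) ln J^2] / (lam+2 mu)``.
    Frame-indifferent (depends on F only through invariants) and zero at F = I.
    """
    lam, mu = params.lame
    beta = params.beta_m
    if beta <= 0:
        raise InvalidParameterError("Holmes-Mow requires beta_m > 0")
    Q = _hm_exponent(state.I1, state.I2, state.J, lam, mu, beta)
    return (lam + 2.0 * mu) / (4.0 * beta) * np.expm1(Q)


def holmes_mow_stress(state: DeformationState, params: MaterialParams):
    """Cauchy stress of the Holmes--Mow matrix (symmetric, zero at F = I)."""
    lam, mu = params.lame
    beta = params.beta_m
    if beta <= 0:
        raise InvalidParameterError("Holmes-Mow requires beta_m > 0")
    F = state.F
    J = np.asarray(state.J)
    B = F @ np.swapaxes(F, -1, -2)
    I1 = np.asarray(state.I1)
    Q = _hm_exponent(I1, state.I2, J, lam, mu, beta)
    eye = np.broadcast_to(np.eye(3), B.shape)
    coef = np.exp(Q) / (2.0 * J)
    sig = (
        ((2.0 * mu - lam) + lam * I1)[..., None, None] * B
        - lam * (B @ B)
        - (lam + 2.0 * mu) * eye
    )
    return coef[..., None, None] * sig


def neo_hookean_energy(state: DeformationState, E: float, nu: float):
    """Compressible Neo-Hookean energy density (used for optional compliant platens)."""
    lam, mu = lame_from_engineering(E, nu)
    lnJ = np.log(state.J)
    return 0.5 * mu * (state.I1 - 3.0) - mu * lnJ + 0.5 * lam * lnJ**2


def neo_hookean_stress(state: DeformationState, E: float, nu: float):
    """Compressible Neo-Hookean Cauchy stress; zero at F = I."""
    lam, mu = lame_from_engineering(E, nu)
    F = state.F
    J = np.asarray(state.J)
    B = F @ np.swapaxes(F, -1, -2)
    eye = np.broadcast_to(np.eye(3), B.shape)
    return (mu / J)[..., None, None] * (B - eye) + (lam * np.log(J) / J)[
        ..., None, None
    ] * eye


def permeability(J, params: MaterialParams):
    """Strain-dependent hydraulic permeability k(J), mm^4/(N s).

    ``k = k0 * ((J - phi0_s)/(1 - phi0_s))^2 * exp(M (J^2 - 1)/2)``;
    strictly increasing in J for M > 0, equal to k0 at J = 1.
    """
    J = np.asarray(J, dtype=float)
    phi0s = params.phi0_s
    if np.any(J <= phi0s):
        raise InvalidParameterError(
            "pore collapse: J must exceed the solid volume fraction"
        )
    ratio = (J - phi0s) / (1.0 - phi0s)
    return params.k0 * ratio**2 * np.exp(0.5 * params.M * (J * J - 1.0))


def fixed_charge_density(J, params: MaterialParams):
    """Instantaneous fixed charge density cF(J) in mM.

    ``cF = phi0_w / (J - 1 + phi0_w) * c0F``: dilutes monotonically as the
    tissue swells, recovering c0F at J = 1 and vanishing as J -> infinity.
    """
    J = np.asarray(J, dtype=float)
    phi0w = params.phi0_w
    denom = J - 1.0 + phi0w
    if np.any(denom <= 0):
        raise InvalidParameterError("J - 1 + phi0_w must be positive")
    return phi0w / denom * params.c0F


def donnan_pressure(cF, env: Environment):
    """Donnan osmotic pressure pi(cF) in MPa (>= 0, increasing in cF).

    ``pi = R T Phi (sqrt(cF^2 + cbar*^2) - cbar*)`` with concentrations in mM.
    """
    cF = np.asarray(cF, dtype=float)
    if np.any(cF < 0):
        raise InvalidParameterError("cF must be >= 0")
    cbar = env.bath_osmolarity
    return env.RT_mpa * (np.sqrt(cF * cF + cbar * cbar) - cbar)


# ---------------------------------------------------------------------------
# Toe-region power-law / linear fiber family
# ---------------------------------------------------------------------------


def _fiber_coefs(E_f: float, lambda0: float, beta_f: float):
    """Toe-branch coefficient xi and toe-end stress/energy for the fiber law."""
    I0 = lambda0 * lambda0
    xi = E_f * (I0 - 1.0) ** (2.0 - beta_f) / (4.0 * beta_f * (beta_f - 1.0))
    psi0 = E_f * (I0 - 1.0) ** 2 / (4.0 * beta_f * (beta_f - 1.0))
    # dPsi/dlambda at the transition stretch (toe side)
    sig0 = E_f * lambda0 * (I0 - 1.0) / (2.0 * (beta_f - 1.0))
    return I0, xi, psi0, sig0


def fiber_energy(lambda_n, params: MaterialParams):
    """Fiber strain-energy density Psi_n(lambda_n) in MPa.

    Piecewise in In = lambda_n^2 with I0 = lambda0^2:

    * slack (In < 1): zero;
    * toe (1 <= In <= I0): ``xi * (In - 1)^beta_f`` with
      ``xi = E_f (I0-1)^(2-beta_f) / (4 beta_f (beta_f - 1))``, reaching
      ``Psi_0 = E_f (I0-1)^2 / (4 beta_f (beta_f-1))`` at the transition;
    * linear (In > I0): stress linear in lambda with slope E_f, energy offset
      by Psi_0 so both branches are continuous at lambda0.

    Branch points are assigned to the toe branch (closed-interval membership).
    """
    if not params.has_fibers:
        raise InvalidParameterError(f"region {params.region_label} carries no fibers")
    lam_n = np.asarray(lambda_n, dtype=float)
    if np.any(lam_n <= 0):
        raise InvalidParameterError("fiber stretch must be positive")
    I0, xi, psi0, sig0 = _fiber_coefs(params.E_f, params.lambda0, params.beta_f)
    In = lam_n * lam_n
    out = np.zeros_like(In)
    toe = (In >= 1.0) & (In <= I0)
    out = np.where(toe, xi * np.abs(In - 1.0) ** params.beta_f, out)
    lin = In > I0
    dl = lam_n - params.lambda0
    out = np.where(lin, psi0 + sig0 * dl + 0.5 * params.E_f * dl * dl, out)
    return out


def fiber_stress_1d(lambda_n, params: MaterialParams):
    """1-D fiber stress dPsi/dlambda in MPa.

    Zero for buckled fibers, power-law toe up to lambda0, then linear with
    slope E_f; continuous at both branch points (C0; the toe-end tangent is
    within a few percent of E_f by construction of the toe coefficient).
    """
    if not params.has_fibers:
        raise InvalidParameterError(f"region {params.region_label} carries no fibers")
    lam_n = np.asarray(lambda_n, dtype=float)
    if np.any(lam_n <= 0):
        raise InvalidParameterError("fiber stretch must be positive")
    I0, xi, _, sig0 = _fiber_coefs(params.E_f, params.lambda0, params.beta_f)
    In = lam_n * lam_n
    bf = params.beta_f
    out = np.zeros_like(In)
    toe = (In >= 1.0) & (In <= I0)
    out = np.where(
        toe, 2.0 * bf * xi * lam_n * np.abs(In - 1.0) ** (bf - 1.0), out
    )
    lin = In > I0
    out = np.where(lin, sig0 + params.E_f * (lam_n - params.lambda0), out)
    return out


def total_cauchy_stress(
    state: DeformationState,
    fiber_stretches,
    params: MaterialParams,
    env: Environment,
    swelling_activation: float = 1.0,
):
    """Total Cauchy stress: matrix + fiber rank-one terms - Donnan pressure.

    ``fiber_stretches`` is an iterable of ``(lambda_n, m_hat)`` pairs where
    ``m_hat`` is the unit fiber direction in the current configuration.  The
    Donnan term uses cF evaluated at the state's J, with the reference fixed
    charge density scaled by ``swelling_activation``.
    """
    sig = holmes_mow_stress(state, params)
    J = np.asarray(state.J)
    eye = np.broadcast_to(np.eye(3), sig.shape)
    if params.c0F > 0 and swelling_activation > 0:
        scaled = MaterialParams(
            region_label=params.region_label,
            E_m=params.E_m,
            nu=params.nu,
            beta_m=params.beta_m,
            k0=params.k0,
            M=params.M,
            c0F=params.c0F * swelling_activation,
            E_f=params.E_f,
            lambda0=params.lambda0,
            theta=params.theta,
            beta_f=params.beta_f,
            phi0_s=params.phi0_s,
        )
        pi = donnan_pressure(fixed_charge_density(J, scaled), env)
        sig = sig - np.asarray(pi)[..., None, None] * eye
    for lam_n, m in fiber_stretches:
        m = np.asarray(m, dtype=float)
        lam_n = np.asarray(lam_n, dtype=float)
        # Cauchy fiber stress: J^-1 lambda dPsi/dlambda m x m
        s1 = fiber_stress_1d(lam_n, params)
        mag = lam_n * s1 / J
        sig = sig + mag[..., None, None] * (m[..., :, None] * m[..., None, :])
    return sig
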