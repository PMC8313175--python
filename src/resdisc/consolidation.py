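"""One-dimensional transient biphasic consolidation.

A confined tissue column (impermeable fixed bottom, free-draining top) is
loaded axially and its settlement history computed by an implicit (backward
Euler) displacement-pressure finite-element scheme with Holmes--Mow
elasticity and strain-dependent Holmes--Mow permeability.  In the
small-strain, constant-permeability limit the response reduces to Terzaghi's
classical consolidation problem, which serves as the analytic benchmark; as
t -> infinity the solution converges to the drained elastic equilibrium.

This reduced-dimension engine is the package's transient demonstrator: the
organ-scale protocols run as drained equilibria, and the permeability law's
dynamic role is exercised here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import DeformationState, MaterialParams, holmes_mow_stress, permeability

__all__ = [
    "ColumnSpec",
    "ConsolidationResult",
    "transient_confined_consolidation",
    "terzaghi_settlement",
    "drained_settlement",
]


@dataclass
class ColumnSpec:
    """Column height (mm) and number of linear elements."""

    height: float = 1.0
    n_elem: int = 40

    def __post_init__(self) -> None:
        if self.height <= 0 or self.n_elem < 2:
            raise ValueError("need positive height and at least 2 elements")


@dataclass
class ConsolidationResult:
    times: np.ndarray
    settlement: np.ndarray  # top-surface downward displacement (mm), >= 0
    params: MaterialParams
    load: float

    @property
    def final(self) -> float:
        return float(self.settlement[-1])


def _sigma_axial(lam_z: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Confined-compression axial Cauchy stress of the Holmes--Mow matrix."""
    lam_z = np.atleast_1d(np.asarray(lam_z, dtype=float))
    F = np.zeros(lam_z.shape + (3, 3))
    F[..., 0, 0] = 1.0
    F[..., 1, 1] = 1.0
    F[..., 2, 2] = lam_z
    return holmes_mow_stress(DeformationState(F=F), params)[..., 2, 2]


def drained_settlement(spec: ColumnSpec, params: MaterialParams, load: float) -> float:
    """Long-time settlement: uniform stretch with sigma_zz = -load (MPa)."""
    from scipy.optimize import brentq

    lam = brentq(
        lambda l: float(_sigma_axial(l, params)[0]) + load, 0.2, 1.5, xtol=1e-14
    )
    return spec.height * (1.0 - lam)


def terzaghi_settlement(times, c_v: float, height: float, s_inf: float, n_terms: int = 200):
    """Analytic Terzaghi settlement series (single-drained column).

    ``U(T) = 1 - sum 2/M^2 exp(-M^2 T)``, ``M = pi (2m+1)/2``,
    ``T = c_v t / H^2``; returns ``s_inf * U``.
    """
    times = np.asarray(times, dtype=float)
    T = c_v * times / height**2
    m = np.arange(n_terms)
    M = 0.5 * np.pi * (2 * m + 1)
    U = 1.0 - (2.0 / M**2 * np.exp(-np.outer(T, M**2))).sum(axis=1)
    return s_inf * U


def transient_confined_consolidation(
    spec: ColumnSpec,
    params: MaterialParams,
    load: float,
    times,
    strain_dependent_k: bool = True,
    max_newton: int = 30,
    tol: float = 1e-11,
    dt_growth: float = 0.05,
) -> ConsolidationResult:
    """Implicit time stepping of the coupled displacement-pressure column.

    ``load`` is the compressive traction (MPa) applied at t = 0+ and held.
    ``times`` are the (strictly increasing, positive) output instants.
    ``strain_dependent_k=False`` freezes the permeability at its reference
    value k0 (the Terzaghi limit).  Internally the backward-Euler step grows
    geometrically (``dt <= dt_growth * t``), which controls the first-order
    time-discretization error uniformly on a log time axis; on Newton failure
    the step is halved.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be positive and strictly increasing")
    n = spec.n_elem
    h = spec.height / n
    # dofs: u at nodes 1..n (u0 = 0 at bottom), p at nodes 0..n-1 (p=0 at top)
    u = np.zeros(n + 1)
    p = np.zeros(n + 1)

    def residual_and_jac(u, p, lam_old, dt):
        lam = 1.0 + np.diff(u) / h
        if np.any(lam <= max(params.phi0_s, 0.05)):
            raise FloatingPointError("pore collapse in consolidation step")
        sig = _sigma_axial(lam, params)
        dsig = (
            _sigma_axial(lam + 1e-7, params) - sig
        ) / 1e-7  # tangent confined modulus
        if strain_dependent_k:
            k = permeability(lam, params)
        else:
            k = np.full(n, params.k0)
        pbar = 0.5 * (p[:-1] + p[1:])
        # momentum residual at free u-nodes 1..n
        Ru = np.zeros(n + 1)
        tot = sig - pbar
        Ru[1:] += tot
        Ru[:-1] -= tot
        Ru[n] += load  # compressive traction at the top
        # continuity residual at p-nodes 0..n-1 (p fixed 0 at node n)
        Rp = np.zeros(n + 1)
        rate = (lam - lam_old) / dt * (0.5 * h)
        Rp[:-1] += rate
        Rp[1:] += rate
        q = k * np.diff(p) / h
        Rp[1:] += q
        Rp[:-1] -= q

        # Jacobian blocks (tridiagonal couplings)
        nn = 2 * (n + 1)
        Jm = np.zeros((nn, nn))
        iu = np.arange(n + 1)
        ip = n + 1 + iu
        for e in range(n):
            a, b = e, e + 1
            ds = dsig[e] / h
            # d Ru / d u
            Jm[iu[b], iu[b]] += ds
            Jm[iu[b], iu[a]] -= ds
            Jm[iu[a], iu[a]] += ds
            Jm[iu[a], iu[b]] -= ds
            # d Ru / d p (through pbar)
            for pn in (a, b):
                Jm[iu[b], ip[pn]] += -0.5
                Jm[iu[a], ip[pn]] -= -0.5
            # d Rp / d u (rate term)
            dl = 1.0 / (h * dt) * (0.5 * h)
            Jm[ip[a], iu[b]] += dl
            Jm[ip[a], iu[a]] -= dl
            Jm[ip[b], iu[b]] += dl
            Jm[ip[b], iu[a]] -= dl
            if strain_dependent_k:
                dk = (
                    permeability(lam[e] + 1e-7, params) - k[e]
                ) / 1e-7
                dq_du = dk * (p[b] - p[a]) / h / h
                Jm[ip[b], iu[b]] += dq_du
                Jm[ip[b], iu[a]] -= dq_du
                Jm[ip[a], iu[b]] -= dq_du
                Jm[ip[a], iu[a]] += dq_du
            # d Rp / d p (flux)
            kk = k[e] / h
            Jm[ip[b], ip[b]] += kk
            Jm[ip[b], ip[a]] -= kk
            Jm[ip[a], ip[a]] += kk
            Jm[ip[a], ip[b]] -= kk
        R = np.concatenate([Ru, Rp])
        return R, Jm, lam

    fixed = np.zeros(2 * (n + 1), dtype=bool)
    fixed[0] = True  # u bottom
    fixed[2 * n + 1] = True  # p top
    free = ~fixed

    def newton_step(uu, pp, lo, dt):
        for _ in range(max_newton):
            R, Jm, _ = residual_and_jac(uu, pp, lo, dt)
            if np.linalg.norm(R[free]) < tol * (1.0 + abs(load)):
                return uu, pp
            Jf = Jm[np.ix_(free, free)]
            dx = np.linalg.solve(Jf, -R[free])
            full = np.zeros(2 * (n + 1))
            full[free] = dx
            uu = uu + full[: n + 1]
            pp = pp + full[n + 1 :]
        raise FloatingPointError("consolidation Newton stalled")

    lam_old = np.ones(n)
    t_now = 0.0
    dt0 = times[0] / 20.0
    settlement = []
    for t_out in times:
        while t_now < t_out - 1e-15 * t_out:
            dt = min(t_out - t_now, max(dt0, dt_growth * t_now))
            halvings = 0
            while True:
                try:
                    u_new, p_new = newton_step(
                        u.copy(), p.copy(), lam_old, dt
                    )
                    break
                except FloatingPointError:
                    dt *= 0.5
                    halvings += 1
                    if halvings > 20:
                        raise RuntimeError(
                            "consolidation time stepping failed to converge"
                        )
            u, p = u_new, p_new
            lam_old = 1.0 + np.diff(u) / h
            t_now += dt
        settlement.append(-u[-1])
    return ConsolidationResult(
        times=times, settlement=np.asarray(settlement), params=params, load=load
    )
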