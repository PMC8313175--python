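"""Quasi-static total-Lagrangian finite-element core.

Trilinear hexahedra with 2x2x2 Gauss quadrature and a classical F-bar
(element-mean dilatation) treatment of the near-incompressible swelling
response.  The residual is exact; element tangent stiffness is obtained by
forward finite differences of the exact element internal-force vector
(24 nodal-dof perturbations, vectorized over all elements), which captures the
F-bar volumetric coupling without a hand-derived consistent tangent.

Constraints are handled by elimination: prescribed dofs carry values, tied
node pairs (the radial cut seam) share reduced dofs through a sparse mapping
``u_full = T u_red + u_prescribed``.  An optional *load-controlled platen*
degree of freedom is solved monolithically through a bordered Newton system.

Everything here is deterministic; there is no randomness anywhere in the
solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh
from .materials import Environment
from .multigen import fiber_direction_global

__all__ = [
    "ConvergenceError",
    "ParamArrays",
    "GenerationGP",
    "FESystem",
    "newton_solve",
    "ramp",
    "centroid_jacobians",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last residual norm."""

    def __init__(self, message: str, residual: float = np.nan):
        super().__init__(message)
        self.residual = residual


# --- reference element -----------------------------------------------------

#: local corner coordinates, standard isoparametric ordering
XI_NODES = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_g = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = np.array(
    [[sx * _g, sy * _g, sz * _g] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
)
GAUSS_WEIGHTS = np.ones(8)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi_j at local points xi, shape (..., 8, 3)."""
    xi = np.atleast_2d(xi)
    out = np.empty(xi.shape[:-1] + (8, 3))
    for a in range(8):
        xa, ya, za = XI_NODES[a]
        out[..., a, 0] = 0.125 * xa * (1 + ya * xi[..., 1]) * (1 + za * xi[..., 2])
        out[..., a, 1] = 0.125 * ya * (1 + xa * xi[..., 0]) * (1 + za * xi[..., 2])
        out[..., a, 2] = 0.125 * za * (1 + xa * xi[..., 0]) * (1 + ya * xi[..., 1])
    return out


_DNDXI_GP = shape_gradients(GAUSS_POINTS)  # (8 gp, 8 nodes, 3)
_DNDXI_C = shape_gradients(np.zeros((1, 3)))[0]  # centroid


def centroid_jacobians(mesh: Mesh) -> np.ndarray:
    """Scaled Jacobian (det J / product of mean edge scales) at centroids."""
    coords = mesh.element_coords()
    Jgeo = np.einsum("nai,aj->nij", coords, _DNDXI_C)
    det = np.linalg.det(Jgeo)
    cols = np.linalg.norm(Jgeo, axis=1)
    return det / np.clip(cols.prod(axis=-1), 1e-30, None)


# --- material parameter fields --------------------------------------------


@dataclass
class ParamArrays:
    """Per-element constitutive constants as broadcastable arrays, plus
    the time-zero fiber directions of the +/-theta families."""

    lam: np.ndarray
    mu: np.ndarray
    beta_m: np.ndarray
    c0F: np.ndarray
    phi0w: np.ndarray
    E_f: np.ndarray
    lam0: np.ndarray
    beta_f: np.ndarray
    has_fibers: np.ndarray
    v_plus: np.ndarray  # (m, 3) time-zero +theta unit direction
    v_minus: np.ndarray

    @classmethod
    def from_mesh(cls, mesh: Mesh) -> "ParamArrays":
        params = mesh.elem_params()
        m = len(params)
        lam = np.empty(m)
        mu = np.empty(m)
        beta_m = np.empty(m)
        c0F = np.empty(m)
        phi0w = np.empty(m)
        E_f = np.zeros(m)
        lam0 = np.full(m, 2.0)  # placeholders keep the vectorized law finite
        beta_f = np.full(m, 2.0)
        hasf = np.zeros(m, dtype=bool)
        axes = mesh.local_axes()
        v_plus = np.zeros((m, 3))
        v_minus = np.zeros((m, 3))
        for e, p in enumerate(params):
            lam[e], mu[e] = p.lame
            beta_m[e] = p.beta_m
            c0F[e] = p.c0F
            phi0w[e] = p.phi0_w
            if p.has_fibers:
                hasf[e] = True
                E_f[e] = p.E_f
                lam0[e] = p.lambda0
                beta_f[e] = p.beta_f
        from .multigen import LocalAxes

        for e, p in enumerate(params):
            if hasf[e]:
                ax = LocalAxes(axes.e1[e], axes.e2[e], axes.e3[e])
                v_plus[e] = fiber_direction_global(ax, p.theta, +1)
                v_minus[e] = fiber_direction_global(ax, p.theta, -1)
        return cls(
            lam=lam[:, None],
            mu=mu[:, None],
            beta_m=beta_m[:, None],
            c0F=c0F[:, None],
            phi0w=phi0w[:, None],
            E_f=E_f[:, None],
            lam0=lam0[:, None],
            beta_f=beta_f[:, None],
            has_fibers=hasf,
            v_plus=v_plus,
            v_minus=v_minus,
        )


@dataclass
class GenerationGP:
    """Solver-level generation record: deposition kinematics per Gauss point.

    ``w`` is F(x,u)^{-1} v_deposition per Gauss point, so that the current
    fiber stretch is simply |F w| and equals exactly 1 at the deposition
    instant.  ``F_centroid`` and ``v_centroid`` support per-element reporting.
    """

    sign: int
    stage: str
    w: np.ndarray  # (m, 8, 3)
    F_centroid: np.ndarray  # (m, 3, 3)
    v_centroid: np.ndarray  # (m, 3) unit deposition direction at centroid


# --- the assembled system ---------------------------------------------------


class FESystem:
    """Mesh + material fields + constraint state + loading state."""

    def __init__(self, mesh: Mesh, env: Optional[Environment] = None):
        if mesh.params is None:
            raise ValueError("assign_region_params before building an FESystem")
        self.mesh = mesh
        self.env = env if env is not None else Environment()
        self.pf = ParamArrays.from_mesh(mesh)

        coords = mesh.element_coords()
        Jgeo = np.einsum("nai,gaj->ngij", coords, _DNDXI_GP)
        detJ = np.linalg.det(Jgeo)
        if np.any(detJ <= 0):
            raise ValueError("mesh has non-positive Jacobians")
        invJ = np.linalg.inv(Jgeo)
        self.gradN = np.einsum("gaj,ngji->ngai", _DNDXI_GP, invJ)  # (m, 8gp, 8a, 3)
        self.wdet = GAUSS_WEIGHTS[None, :] * detJ  # (m, 8)
        Jg0 = np.einsum("nai,aj->nij", coords, _DNDXI_C)
        self.gradN0 = np.einsum("aj,nji->nai", _DNDXI_C, np.linalg.inv(Jg0))
        self.elem_vol = self.wdet.sum(axis=1)

        n = mesh.n_nodes
        self.n_dof = 3 * n
        self.u = np.zeros((n, 3))
        self.f_ext = np.zeros((n, 3))
        self.prescribed = np.zeros((n, 3), dtype=bool)
        self.presc_val = np.zeros((n, 3))
        self.ties_active = not mesh.cut_released

        # loading state
        self.alpha = 0.0  # swelling activation scaling all c0F
        self.fiber_scale = 1.0
        self.generations: list[GenerationGP] = []
        # optional stabilization: weak springs to an anchor configuration,
        # ramped to zero across constraint-release stages
        self.spring_k = 0.0
        self.spring_anchor: Optional[np.ndarray] = None  # (n_dof,)

        edof = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(-1, 24)
        self._rows = np.repeat(edof, 24, axis=1).ravel()
        self._cols = np.tile(edof, (1, 24)).ravel()
        self._edof = edof
        self._T_cache = None

    # -- constraint bookkeeping --

    def invalidate_constraints(self) -> None:
        self._T_cache = None

    def set_prescribed(self, nodes: np.ndarray, comps, values) -> None:
        """Prescribe components ``comps`` of ``nodes`` to ``values`` ((len(nodes), len(comps)) or scalar)."""
        values = np.broadcast_to(
            np.asarray(values, dtype=float), (len(nodes), len(comps))
        )
        for j, c in enumerate(comps):
            self.prescribed[nodes, c] = True
            self.presc_val[nodes, c] = values[:, j]
        self.invalidate_constraints()

    def free_nodes(self, nodes: np.ndarray, comps=(0, 1, 2)) -> None:
        for c in comps:
            self.prescribed[nodes, c] = False
        self.invalidate_constraints()

    def master_of(self) -> np.ndarray:
        """Per-node master index (identity unless a tied cut slave)."""
        n = self.mesh.n_nodes
        master = np.arange(n)
        if self.ties_active and len(self.mesh.cut_pairs):
            a, b = self.mesh.cut_pairs[:, 0], self.mesh.cut_pairs[:, 1]
            master[b] = a
        return master

    def reduction(self):
        """Sparse T (n_dof x n_red) and prescribed full-vector; cached."""
        if self._T_cache is not None:
            return self._T_cache
        master = self.master_of()
        presc = self.prescribed.copy()
        vals = self.presc_val.copy()
        # a slave inherits its master's prescribed state
        slave = master != np.arange(self.mesh.n_nodes)
        presc[slave] = presc[master[slave]]
        vals[slave] = vals[master[slave]]

        red_index = -np.ones((self.mesh.n_nodes, 3), dtype=np.int64)
        k = 0
        for node in range(self.mesh.n_nodes):
            if master[node] != node:
                continue
            for c in range(3):
                if not presc[node, c]:
                    red_index[node, c] = k
                    k += 1
        red_index[slave] = red_index[master[slave]]
        free = (red_index >= 0).ravel()
        rows = np.nonzero(free)[0]
        cols = red_index.ravel()[free]
        T = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n_dof, k)
        )
        u_presc = np.where(free, 0.0, vals.ravel())
        self._T_cache = (T, u_presc, red_index)
        return self._T_cache

    def apply_prescribed(self) -> None:
        """Push prescribed/tied values into the displacement field."""
        T, u_presc, red_index = self.reduction()
        u_flat = self.u.ravel().copy()
        fixed = red_index.ravel() < 0
        u_flat[fixed] = u_presc[fixed]
        # tied free dofs copy their master's current value
        master = self.master_of()
        slave = np.nonzero(master != np.arange(self.mesh.n_nodes))[0]
        u = u_flat.reshape(-1, 3)
        u[slave] = u[master[slave]]
        self.u = u

    # -- kinematics and residual --

    def deformation_gradients(self, u_e: np.ndarray, fbar: bool = True):
        """F (and element-mean J) at all Gauss points from element dofs (m,8,3)."""
        F = np.einsum("mai,mgaj->mgij", u_e, self.gradN)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise FloatingPointError("element inversion during trial step")
        if fbar:
            Jbar = (self.wdet * J).sum(axis=1) / self.wdet.sum(axis=1)
            scale = np.cbrt(np.clip(Jbar[:, None] / J, 1e-8, 1e8))
            F = scale[..., None, None] * F
            J = np.broadcast_to(Jbar[:, None], J.shape).copy()
        return F, J

    def centroid_F(self, fbar_consistent: bool = True) -> np.ndarray:
        """Per-element deformation gradient at the centroid (mean-dilatation scaled)."""
        u_e = self.u[self.mesh.elems]
        F = np.einsum("mai,maj->mij", u_e, self.gradN0)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        if fbar_consistent:
            Fg, _ = self.deformation_gradients(u_e, fbar=False)
            Jg = np.linalg.det(Fg)
            Jbar = (self.wdet * Jg).sum(axis=1) / self.wdet.sum(axis=1)
            J = np.linalg.det(F)
            F = np.cbrt(np.clip(Jbar / J, 1e-8, 1e8))[:, None, None] * F
        return F

    def piola(self, F: np.ndarray, J: np.ndarray) -> np.ndarray:
        """First Piola-Kirchhoff stress at Gauss points (m, 8, 3, 3)."""
        pf = self.pf
        lam, mu, beta = pf.lam, pf.mu, pf.beta_m
        Ft = np.swapaxes(F, -1, -2)
        B = F @ Ft
        I1 = np.trace(B, axis1=-2, axis2=-1)
        trB2 = np.einsum("...ij,...ji->...", B, B)
        I2 = 0.5 * (I1 * I1 - trB2)
        lnJ = np.log(J)
        Q = beta * ((2 * mu - lam) * (I1 - 3) + lam * (I2 - 3)) / (
            lam + 2 * mu
        ) - 2 * beta * lnJ
        eQ = np.exp(np.clip(Q, -60.0, 60.0))
        eye = np.eye(3)
        JsF = 0.5 * eQ[..., None, None] * (
            ((2 * mu - lam) + lam * I1)[..., None, None] * B
            - lam[..., None, None] * (B @ B)
            - (lam + 2 * mu)[..., None, None] * eye
        )  # J * sigma
        FinvT = np.swapaxes(np.linalg.inv(F), -1, -2)
        P = JsF @ FinvT

        if self.alpha > 0:
            c0 = pf.c0F * self.alpha
            denom = np.clip(J - 1.0 + pf.phi0w, 1e-6, None)
            cF = pf.phi0w / denom * c0
            cbar = self.env.bath_osmolarity
            pi = self.env.RT_mpa * (np.sqrt(cF * cF + cbar * cbar) - cbar)
            P = P - (pi * J)[..., None, None] * FinvT

        if self.fiber_scale > 0 and self.generations:
            for gen in self.generations:
                Fw = np.einsum("mgij,mgj->mgi", F, gen.w)
                lam_n = np.linalg.norm(Fw, axis=-1)
                s1 = self._fiber_dpsi(lam_n)
                coef = np.where(lam_n > 1.0, s1 / np.clip(lam_n, 1e-9, None), 0.0)
                coef = coef * self.fiber_scale
                P = P + coef[..., None, None] * (
                    Fw[..., :, None] * gen.w[..., None, :]
                )
        return P

    def _fiber_dpsi(self, lam_n: np.ndarray) -> np.ndarray:
        """Vectorized dPsi/dlambda of the toe/linear fiber law (zero if slack
        or region fiber-free)."""
        pf = self.pf
        Ef, lam0, bf = pf.E_f, pf.lam0, pf.beta_f
        I0 = lam0 * lam0
        xi = Ef * (I0 - 1.0) ** (2.0 - bf) / (4.0 * bf * (bf - 1.0))
        sig0 = Ef * lam0 * (I0 - 1.0) / (2.0 * (bf - 1.0))
        In = lam_n * lam_n
        toe = 2.0 * bf * xi * lam_n * np.abs(In - 1.0) ** (bf - 1.0)
        lin = sig0 + Ef * (lam_n - lam0)
        out = np.where(In <= I0, toe, lin)
        out = np.where(In < 1.0, 0.0, out)
        out = np.where(pf.has_fibers[:, None], out, 0.0)
        return out

    def element_forces(self, u_e: np.ndarray) -> np.ndarray:
        F, J = self.deformation_gradients(u_e)
        P = self.piola(F, J)
        return np.einsum("mg,mgij,mgaj->mai", self.wdet, P, self.gradN)

    def internal_forces(self, u: Optional[np.ndarray] = None) -> np.ndarray:
        if u is None:
            u = self.u
        f_e = self.element_forces(u[self.mesh.elems])
        out = self._scatter(f_e)
        if self.spring_k > 0.0 and self.spring_anchor is not None:
            out = out + self.spring_k * (u - self.spring_anchor.reshape(-1, 3))
        return out

    def _scatter(self, f_e: np.ndarray) -> np.ndarray:
        n = self.mesh.n_nodes
        idx = self.mesh.elems.ravel()
        out = np.empty((n, 3))
        for c in range(3):
            out[:, c] = np.bincount(idx, weights=f_e[:, :, c].ravel(), minlength=n)
        return out

    def internal_force_scale(self) -> float:
        """Sum of |element force contributions| per dof: residual reference."""
        u_e = self.u[self.mesh.elems]
        try:
            f_e = self.element_forces(u_e)
        except FloatingPointError:
            return 1.0
        n = self.mesh.n_nodes
        idx = self.mesh.elems.ravel()
        tot = 0.0
        for c in range(3):
            s = np.bincount(idx, weights=np.abs(f_e[:, :, c]).ravel(), minlength=n)
            tot += (s * s).sum()
        return float(np.sqrt(tot))

    def tangent(self, h: float = 1e-7) -> sp.csr_matrix:
        u_e = self.u[self.mesh.elems]
        f0 = self.element_forces(u_e)
        m = u_e.shape[0]
        K = np.empty((m, 24, 24))
        for a in range(8):
            for c in range(3):
                up = u_e.copy()
                up[:, a, c] += h
                fp = self.element_forces(up)
                K[:, :, 3 * a + c] = ((fp - f0) / h).reshape(m, 24)
        Kmat = sp.coo_matrix(
            (K.ravel(), (self._rows, self._cols)), shape=(self.n_dof, self.n_dof)
        ).tocsr()
        if self.spring_k > 0.0 and self.spring_anchor is not None:
            Kmat = Kmat + self.spring_k * sp.identity(self.n_dof, format="csr")
        return Kmat

    def stiffness_scale(self) -> float:
        """Median diagonal tangent stiffness (N/mm): stabilization reference."""
        K = self.tangent()
        d = K.diagonal()
        d = d[d > 0]
        return float(np.median(d)) if len(d) else 1.0

    # -- strain energy (work-energy diagnostics) --

    def strain_energy(self) -> float:
        """Total stored energy (matrix + fibers + Donnan potential), N mm."""
        from scipy.integrate import fixed_quad

        u_e = self.u[self.mesh.elems]
        F, J = self.deformation_gradients(u_e)
        pf = self.pf
        lam, mu, beta = pf.lam, pf.mu, pf.beta_m
        B = F @ np.swapaxes(F, -1, -2)
        I1 = np.trace(B, axis1=-2, axis2=-1)
        trB2 = np.einsum("...ij,...ji->...", B, B)
        I2 = 0.5 * (I1 * I1 - trB2)
        Q = beta * ((2 * mu - lam) * (I1 - 3) + lam * (I2 - 3)) / (
            lam + 2 * mu
        ) - 2 * beta * np.log(J)
        W = (lam + 2 * mu) / (4 * beta) * np.expm1(Q)
        if self.fiber_scale > 0 and self.generations:
            Ef, lam0, bf = pf.E_f, pf.lam0, pf.beta_f
            I0 = lam0 * lam0
            xi = Ef * (I0 - 1.0) ** (2.0 - bf) / (4.0 * bf * (bf - 1.0))
            psi0 = Ef * (I0 - 1.0) ** 2 / (4.0 * bf * (bf - 1.0))
            sig0 = Ef * lam0 * (I0 - 1.0) / (2.0 * (bf - 1.0))
            for gen in self.generations:
                Fw = np.einsum("mgij,mgj->mgi", F, gen.w)
                ln = np.linalg.norm(Fw, axis=-1)
                In = ln * ln
                toe = xi * np.abs(In - 1.0) ** bf
                dl = ln - lam0
                linb = psi0 + sig0 * dl + 0.5 * Ef * dl * dl
                psi = np.where(In <= I0, toe, linb)
                psi = np.where(In < 1.0, 0.0, psi)
                psi = np.where(pf.has_fibers[:, None], psi, 0.0)
                W = W + self.fiber_scale * psi
        if self.alpha > 0:
            cbar = self.env.bath_osmolarity
            RT = self.env.RT_mpa

            def neg_pi(j, c0, phi0w):
                cF = phi0w / (j - 1.0 + phi0w) * c0
                return -RT * (np.sqrt(cF * cF + cbar * cbar) - cbar)

            c0 = (pf.c0F * self.alpha)[:, 0]
            phi0w = pf.phi0w[:, 0]
            Udon = np.zeros_like(J)
            for e in range(J.shape[0]):
                if c0[e] <= 0:
                    continue
                for g in range(J.shape[1]):
                    val, _ = fixed_quad(
                        neg_pi, 1.0, J[e, g], args=(c0[e], phi0w[e]), n=24
                    )
                    Udon[e, g] = val
            W = W + Udon
        return float((self.wdet * W).sum())

    # -- reactions --

    def residual(self) -> np.ndarray:
        return self.internal_forces() - self.f_ext

    def reaction(self, nodes: np.ndarray) -> np.ndarray:
        """Net force the constraint must supply at ``nodes`` (n_sel, 3)."""
        r = self.residual()
        return r[nodes]

    def platen_force_z(self, surface: str = "superior") -> float:
        return float(self.reaction(self.mesh.node_sets[surface])[:, 2].sum())

    def platen_torque_z(self, surface: str = "superior") -> float:
        nodes = self.mesh.node_sets[surface]
        r = self.reaction(nodes)
        x = self.mesh.nodes[nodes] + self.u[nodes]
        return float((x[:, 0] * r[:, 1] - x[:, 1] * r[:, 0]).sum())


# --- Newton solver ----------------------------------------------------------


def newton_solve(
    sys: FESystem,
    tol_rel: float = 1e-8,
    tol_abs: float = 1e-9,
    max_iter: int = 25,
    platen_g: Optional[np.ndarray] = None,
    platen_target: Optional[float] = None,
    reuse_tangent: int = 1,
) -> dict:
    """Solve for equilibrium at the current prescribed/loading state.

    If ``platen_g`` (a full-dof indicator vector) and ``platen_target`` are
    given, the corresponding rigid-platen translation is an extra unknown and
    the generalized residual g.(f_int - f_ext) - platen_target is driven to
    zero monolithically (bordered Newton system).
    """
    sys.apply_prescribed()
    T, u_presc, red_index = sys.reduction()
    scale = max(sys.internal_force_scale(), 1e-8)
    lu = None
    K = None
    info = {"iterations": 0, "residual": np.inf}

    def residual_red(u_flat):
        sys.u = u_flat.reshape(-1, 3)
        r = (sys.internal_forces() - sys.f_ext).ravel()
        rr = T.T @ r
        extra = None
        if platen_g is not None:
            extra = float(platen_g @ r) - platen_target
        return r, rr, extra

    u_flat = sys.u.ravel().copy()
    r, rr, extra = residual_red(u_flat)
    for it in range(max_iter + 1):
        res_norm = np.linalg.norm(rr)
        if extra is not None:
            res_norm = np.hypot(res_norm, abs(extra))
        info.update(iterations=it, residual=float(res_norm))
        if res_norm <= tol_abs + tol_rel * scale:
            sys.u = u_flat.reshape(-1, 3)
            return info
        if it == max_iter:
            break
        if lu is None or it % max(reuse_tangent, 1) == 0:
            sys.u = u_flat.reshape(-1, 3)
            K = sys.tangent()
            Kr = (T.T @ K @ T).tocsc()
            lu = spla.splu(Kr)
        if platen_g is not None:
            Krg = T.T @ (K @ platen_g)  # column coupling dR_r/d(dz)
            Kgr = T.T @ (K.T @ platen_g)  # row coupling dR_g/du (K is not
            # exactly symmetric: finite-difference tangent)
            x1 = lu.solve(-rr)
            x2 = lu.solve(Krg)
            kgg = float(platen_g @ (K @ platen_g))
            denom = kgg - float(Kgr @ x2)
            if abs(denom) < 1e-30:
                raise ConvergenceError("singular platen coupling", res_norm)
            ddz = -(extra + float(Kgr @ x1)) / denom
            du_red = x1 - x2 * ddz
        else:
            du_red = lu.solve(-rr)
            ddz = 0.0

        du_full = T @ du_red
        if platen_g is not None:
            du_full = du_full + ddz * platen_g
        # backtracking line search on the residual norm
        trial = None
        trial_step = None
        step = 1.0
        for _ in range(10):
            try:
                trial = residual_red(u_flat + step * du_full)
                trial_step = step
            except FloatingPointError:
                step *= 0.5
                continue
            new_norm = np.linalg.norm(trial[1])
            if trial[2] is not None:
                new_norm = np.hypot(new_norm, abs(trial[2]))
            if new_norm <= max(
                res_norm * (1.0 - 1e-4 * step), tol_abs + tol_rel * scale
            ):
                break
            step *= 0.5
        if trial is None:
            raise ConvergenceError("line search failed (element inversion)", res_norm)
        # accept the (possibly damped) step even without decrease: helps
        # escape mild stagnation; the substep driver handles true failures
        u_flat = u_flat + trial_step * du_full
        r, rr, extra = trial

    raise ConvergenceError(
        f"Newton did not converge in {max_iter} iterations "
        f"(residual {info['residual']:.3e}, scale {scale:.3e})",
        info["residual"],
    )


def ramp(
    sys: FESystem,
    set_fraction: Callable[[float], None],
    n_sub: int = 10,
    max_halvings: int = 10,
    grow: float = 1.5,
    **newton_kw,
) -> None:
    """Drive a loading parameter from its current state to 1 in substeps.

    ``set_fraction(s)`` must update the system (prescribed values, swelling
    activation, external forces ...) for fraction ``s`` in [0, 1].  On
    non-convergence the substep is halved adaptively; on easy convergence it
    grows again, capped at the nominal 1/n_sub.
    """
    s = 0.0
    ds = 1.0 / n_sub
    ds_cap = ds
    ds_min = ds / 2**max_halvings
    u_saved = sys.u.copy()
    while s < 1.0 - 1e-12:
        s_try = min(1.0, s + ds)
        set_fraction(s_try)
        try:
            info = newton_solve(sys, **newton_kw)
        except ConvergenceError:
            sys.u = u_saved.copy()
            ds *= 0.5
            # once a level fails, do not regrow past it again
            ds_cap = ds
            if ds < ds_min:
                raise
            continue
        s = s_try
        u_saved = sys.u.copy()
        if info["iterations"] <= 5:
            ds = min(ds * grow, ds_cap)
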