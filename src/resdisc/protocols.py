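"""Loading protocols: swelling, multigenerational fiber deposition, preload,
the organ-scale test cases, and the radial-incision experiment.

A :class:`DiscSimulation` wraps an :class:`~resdisc.fem.FESystem` between two
rigid platens (inferior fixed, superior driven).  All protocols are sequences
of drained (Donnan-equilibrated) quasi-static solves: the long preload hold
and the slow load/rotation ramps are represented by their fluid-equilibrated
limits.  Rate-dependent cases therefore run at reduced fidelity, flagged
``mode='drained_sequence'`` in the returned curve metadata; the strain-
dependent permeability law is exercised separately by the one-dimensional
transient consolidation engine (:mod:`resdisc.consolidation`).

The multigeneration deposition protocol mirrors the residual-strain recipe:
swell (optionally ramping the height by ``dH``), twist the superior platen to
``-Omega`` and record the +theta fiber family in that configuration with
negligible modulus, return to neutral, twist to ``+Omega`` and record the
-theta family, return to neutral, then ramp the fiber modulus to full value
under fixed boundary conditions.  The swelling-only model instead records
both families at time zero (classical fiber model) before swelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fem import ConvergenceError, FESystem, GenerationGP, newton_solve, ramp
from .geometry import Mesh, release_cut
from .materials import Environment
from .metrics import Curve
from .multigen import FiberField

__all__ = [
    "DiscSimulation",
    "equilibrium_solve",
    "swell_to_equilibrium",
    "run_multigen_deposition",
    "apply_preload",
    "run_test_case",
    "simulate_incision",
    "TEST_CASES",
]

TEST_CASES = (
    "slow_ramp",
    "creep",
    "stress_relaxation",
    "axial_compression",
    "torsion",
    "bending",
    "flexion",
)


def _rot(rz: float, ry: float, rx: float) -> np.ndarray:
    """Rotation matrix Rz(rz) Ry(ry) Rx(rx), angles in degrees."""
    cz, sz = np.cos(np.deg2rad(rz)), np.sin(np.deg2rad(rz))
    cy, sy = np.cos(np.deg2rad(ry)), np.sin(np.deg2rad(ry))
    cx, sx = np.cos(np.deg2rad(rx)), np.sin(np.deg2rad(rx))
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx


@dataclass
class PlatenState:
    """Rigid superior-platen pose: axial translation (mm) and rotations (deg)."""

    dz: float = 0.0
    rot_z: float = 0.0
    rot_y: float = 0.0
    rot_x: float = 0.0


class DiscSimulation:
    """A disc model between rigid platens, driven through loading protocols."""

    def __init__(
        self,
        mesh: Mesh,
        env: Optional[Environment] = None,
        mode: str = "swelling_only",
        newton_kw: Optional[dict] = None,
    ):
        if mode not in ("swelling_only", "multigen"):
            raise ValueError("mode must be 'swelling_only' or 'multigen'")
        self.sys = FESystem(mesh, env)
        self.mode = mode
        self.platen = PlatenState()
        self.platens_bonded = False
        self.newton_kw = dict(tol_rel=1e-8, tol_abs=1e-9, max_iter=25)
        if newton_kw:
            self.newton_kw.update(newton_kw)
        self.stage_history: list[str] = []
        self._platen_zero_force = False
        self._center_top = np.array([0.0, 0.0, float(mesh.nodes[:, 2].max())])
        if mode == "swelling_only":
            self._deposit_both_at_time_zero()
        self.sys.fiber_scale = 1.0 if mode == "swelling_only" else 0.0
        self.bond_platens()

    # ------------------------------------------------------------------ BCs

    def bond_platens(self) -> None:
        """Bond inferior (fixed) and superior (posed) surfaces to rigid platens."""
        mesh = self.sys.mesh
        inf = mesh.node_sets["inferior"]
        sup = mesh.node_sets["superior"]
        self.sys.set_prescribed(inf, (0, 1, 2), 0.0)
        self.sys.set_prescribed(sup, (0, 1, 2), self._platen_disp(sup))
        self.platens_bonded = True

    def _platen_disp(self, nodes: np.ndarray, platen: Optional[PlatenState] = None):
        p = platen if platen is not None else self.platen
        X = self.sys.mesh.nodes[nodes]
        R = _rot(p.rot_z, p.rot_y, p.rot_x)
        c = self._center_top
        u = (X - c) @ R.T + c - X
        u[:, 2] += p.dz
        return u

    def _set_platen(self, **pose) -> None:
        for k, v in pose.items():
            setattr(self.platen, k, v)
        if self.platens_bonded:
            sup = self.sys.mesh.node_sets["superior"]
            self.sys.set_prescribed(sup, (0, 1, 2), self._platen_disp(sup))

    def solve(self, **kw) -> dict:
        merged = {**self.newton_kw, **kw}
        return newton_solve(self.sys, **merged)

    def _release_kw(self) -> dict:
        # constraint-release stages traverse soft, nearly-unconstrained
        # configurations: give Newton more room before substep halving, but
        # fail fast enough that adaptive halving stays affordable
        kw = dict(self.newton_kw)
        kw["max_iter"] = max(kw.get("max_iter", 25), 35)
        return kw

    # ------------------------------------------------------------- swelling

    def swell(self, dH: float = 0.0, n_sub: int = 10) -> None:
        """Ramp all fixed charge densities to full value (Donnan equilibrium).

        ``dH`` simultaneously ramps the superior platen height change (the
        multigeneration protocol increases the disc height while it swells);
        the swelling-only protocol holds the height fixed (dH = 0).
        """
        base_dz = self.platen.dz

        def set_fraction(s: float) -> None:
            self.sys.alpha = s
            self._set_platen(dz=base_dz + s * dH)

        ramp(self.sys, set_fraction, n_sub=n_sub, **self.newton_kw)
        self.stage_history.append(f"swell(dH={dH})")

    # ------------------------------------------- multigeneration deposition

    def _deposition_record(self, sign: int, stage: str) -> GenerationGP:
        sys = self.sys
        pf = sys.pf
        v0 = pf.v_plus if sign > 0 else pf.v_minus  # (m, 3) zero if fiber-free
        u_e = sys.u[sys.mesh.elems]
        F_gp, _ = sys.deformation_gradients(u_e)  # F-bar at Gauss points
        v = np.einsum("mgij,mj->mgi", F_gp, v0)
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        v_dep = np.where(norm > 0, v / np.clip(norm, 1e-30, None), 0.0)
        w = np.einsum("mgij,mgj->mgi", np.linalg.inv(F_gp), v_dep)
        F_c = sys.centroid_F()
        vc = np.einsum("mij,mj->mi", F_c, v0)
        nc = np.linalg.norm(vc, axis=-1, keepdims=True)
        v_cent = np.where(nc > 0, vc / np.clip(nc, 1e-30, None), 0.0)
        return GenerationGP(sign=sign, stage=stage, w=w, F_centroid=F_c, v_centroid=v_cent)

    def _deposit_both_at_time_zero(self) -> None:
        """Classical fiber model: both +/-theta families referenced at time zero."""
        sys = self.sys
        m = sys.mesh.n_elems
        eyeF = np.broadcast_to(np.eye(3), (m, 3, 3)).copy()
        for sign, v0 in ((+1, sys.pf.v_plus), (-1, sys.pf.v_minus)):
            w = np.broadcast_to(v0[:, None, :], (m, 8, 3)).copy()
            sys.generations.append(
                GenerationGP(
                    sign=sign, stage="time_zero", w=w, F_centroid=eyeF, v_centroid=v0.copy()
                )
            )

    def twist_to(self, angle_deg: float, n_sub: int = 4) -> None:
        """Rotate the superior platen about the spinal axis to ``angle_deg``."""
        start = self.platen.rot_z

        def set_fraction(s: float) -> None:
            self._set_platen(rot_z=start + s * (angle_deg - start))

        ramp(self.sys, set_fraction, n_sub=n_sub, **self.newton_kw)

    def run_multigen_deposition(self, omega: float, n_sub: int = 4) -> None:
        """Deposit two pre-strained fiber families by twisting to -/+ Omega.

        Requires ``mode='multigen'`` and a swollen state.  After both families
        are recorded the fiber modulus is ramped from (exactly) zero to full
        value under fixed boundary conditions.
        """
        if self.mode != "multigen":
            raise ValueError("deposition requires mode='multigen'")
        if self.sys.generations:
            raise ValueError("generations already deposited")
        if omega != 0.0:
            self.twist_to(-omega, n_sub=n_sub)
        self.sys.generations.append(self._deposition_record(+1, f"twist(-{omega})"))
        if omega != 0.0:
            self.twist_to(0.0, n_sub=n_sub)
        if omega != 0.0:
            self.twist_to(+omega, n_sub=n_sub)
        self.sys.generations.append(self._deposition_record(-1, f"twist(+{omega})"))
        if omega != 0.0:
            self.twist_to(0.0, n_sub=n_sub)

        def set_fraction(s: float) -> None:
            self.sys.fiber_scale = s

        ramp(self.sys, set_fraction, n_sub=10, **self.newton_kw)
        self.stage_history.append(f"multigen_deposition(omega={omega})")

    # -------------------------------------------------------------- preload

    def _platen_g(self) -> np.ndarray:
        g = np.zeros(self.sys.n_dof)
        sup = self.sys.mesh.node_sets["superior"]
        g[3 * sup + 2] = 1.0
        return g

    def apply_preload(self, load: float, n_sub: int = 4) -> None:
        """Equilibrate to a compressive axial force (N) on the superior platen.

        Axial force is the only controlled platen degree of freedom; all
        others stay fixed.  The hold period is represented by the drained
        equilibrium solution.
        """
        if load == 0.0:
            return
        g = self._platen_g()
        target0 = self.platen_force()
        s_done = 0.0
        ds = 1.0 / n_sub
        u_saved = self.sys.u.copy()
        while s_done < 1.0 - 1e-12:
            s = min(1.0, s_done + ds)
            target = target0 + s * (-load - target0)
            try:
                self.solve(platen_g=g, platen_target=target)
            except ConvergenceError:
                self.sys.u = u_saved.copy()
                ds *= 0.5
                if ds < 1.0 / (n_sub * 2**7):
                    raise
                continue
            s_done = s
            u_saved = self.sys.u.copy()
        # lock the achieved translation in as the new platen pose
        sup = self.sys.mesh.node_sets["superior"]
        dz = float(np.mean(self.sys.u[sup, 2] - self._platen_disp(sup)[:, 2])) + self.platen.dz
        self._set_platen(dz=dz)
        self.stage_history.append(f"preload({load} N)")

    def platen_force(self) -> float:
        """Axial force (N, + tension) currently transmitted by the superior platen."""
        return self.sys.platen_force_z("superior")

    def platen_moment(self, axis: int) -> float:
        """Moment (N mm) of the superior-platen reaction about ``axis`` through
        the platen center."""
        sys = self.sys
        nodes = sys.mesh.node_sets["superior"]
        r = sys.reaction(nodes)
        x = sys.mesh.nodes[nodes] + sys.u[nodes] - self._center_top
        mom = np.cross(x, r).sum(axis=0)
        return float(mom[axis])

    # ------------------------------------------------------------ test cases

    def run_test_case(self, case: str, scale: float = 1.0, n_steps: int = 8) -> Curve:
        """Run one organ-scale protocol; returns the control/response curve.

        ``scale`` uniformly scales the target load/rotation/compression (for
        scaled-down runs); sampling is ``n_steps`` drained equilibria.
        """
        if case not in TEST_CASES:
            raise ValueError(f"unknown test case {case!r}")
        meta = {"case": case, "mode": "drained_sequence", "model": self.mode}
        if case in ("slow_ramp", "creep"):
            target = (2000.0 if case == "slow_ramp" else 1000.0) * scale
            rate = 1.0 if case == "slow_ramp" else 200.0
            return self._force_ramp_curve(target, rate, n_steps, meta)
        if case == "stress_relaxation":
            self.apply_preload(50.0 * scale)
            H = self.sys.mesh.nodes[:, 2].max()
            return self._displacement_ramp_curve(-0.05 * H * scale, n_steps, meta)
        if case == "axial_compression":
            return self._force_ramp_curve(900.0 * scale, 18.0, n_steps, meta)
        axis = {"torsion": 2, "bending": 1, "flexion": 0}[case]
        attr = {"torsion": "rot_z", "bending": "rot_y", "flexion": "rot_x"}[case]
        return self._rotation_ramp_curve(attr, axis, 3.0 * scale, n_steps, meta)

    def _force_ramp_curve(self, target: float, rate: float, n_steps: int, meta) -> Curve:
        g = self._platen_g()
        f0 = self.platen_force()
        sup = self.sys.mesh.node_sets["superior"]
        z0 = float(np.mean(self.sys.u[sup, 2]))
        xs, ys = [0.0], [0.0]
        for k in range(1, n_steps + 1):
            tgt = f0 + k * (-target - f0) / n_steps
            self.solve(platen_g=g, platen_target=tgt)
            dz = float(np.mean(self.sys.u[sup, 2])) - z0
            xs.append(-tgt / rate)
            ys.append(-dz)  # compressive displacement positive
        dzf = float(np.mean(self.sys.u[sup, 2] - self._platen_disp(sup)[:, 2])) + self.platen.dz
        self._set_platen(dz=dzf)
        meta = {**meta, "control": "axial load (N)", "response": "compression (mm)"}
        return Curve(x=np.asarray(xs), y_model=np.asarray(ys), meta=meta)

    def _displacement_ramp_curve(self, dz_target: float, n_steps: int, meta) -> Curve:
        base = self.platen.dz
        xs, ys = [0.0], [-self.platen_force()]
        for k in range(1, n_steps + 1):
            self._set_platen(dz=base + k * dz_target / n_steps)
            self.solve()
            xs.append(abs(k * dz_target / n_steps))
            ys.append(-self.platen_force())
        meta = {**meta, "control": "compression (mm)", "response": "axial force (N)"}
        return Curve(x=np.asarray(xs), y_model=np.asarray(ys), meta=meta)

    def _rotation_ramp_curve(self, attr: str, axis: int, angle: float, n_steps: int, meta) -> Curve:
        xs, ys = [0.0], [0.0]
        m0 = self.platen_moment(axis)
        for k in range(1, n_steps + 1):
            a = k * angle / n_steps
            def set_fraction(s, a=a, prev=getattr(self.platen, attr)):
                self._set_platen(**{attr: prev + s * (a - prev)})
            ramp(self.sys, set_fraction, n_sub=1, **self.newton_kw)
            xs.append(a)
            ys.append(self.platen_moment(axis) - m0)
        meta = {**meta, "control": f"rotation about axis {axis} (deg)", "response": "moment (N mm)"}
        return Curve(x=np.asarray(xs), y_model=np.asarray(ys), meta=meta)

    # -------------------------------------------------------------- incision

    def _ramped_release(
        self, counter: np.ndarray, n_sub: int, extra_newton: Optional[dict] = None
    ) -> None:
        """Ramp released-constraint reactions to zero along an equilibrium path.

        Stabilized with weak springs to the last converged configuration whose
        stiffness ramps down with the reactions and vanishes at full release,
        so the final state is an exact unstabilized equilibrium.
        """
        sys = self.sys
        f0 = sys.f_ext.copy()
        k0 = 0.15 * sys.stiffness_scale()
        u_anchor = sys.u.ravel().copy()
        kw = self._release_kw()
        if extra_newton:
            kw.update(extra_newton)
        s, ds = 0.0, 1.0 / n_sub
        ds_cap, ds_min = ds, ds / 2**10
        u_saved = sys.u.copy()
        while s < 1.0 - 1e-12:
            s_try = min(1.0, s + ds)
            sys.f_ext = f0 + (1.0 - s_try) * counter
            sys.spring_k = k0 * (1.0 - s_try)
            sys.spring_anchor = u_anchor
            try:
                info = newton_solve(sys, **kw)
            except ConvergenceError:
                sys.u = u_saved.copy()
                ds *= 0.5
                ds_cap = ds
                if ds < ds_min:
                    sys.f_ext = f0
                    sys.spring_k = 0.0
                    raise
                continue
            s = s_try
            u_saved = sys.u.copy()
            u_anchor = sys.u.ravel().copy()
            if info["iterations"] <= 5:
                ds = min(ds * 1.5, ds_cap)
        sys.f_ext = f0
        sys.spring_k = 0.0
        sys.spring_anchor = None

    def release_platens(self, n_sub: int = 8, mode: str = "zero_force") -> None:
        """Release the platens' grip on the disc before the incision.

        The incision experiment is performed on discs isolated from their
        endplates, so the bonded platen constraint must not pin the annulus
        wall.  Modes:

        * ``"zero_force"`` (default): platens become rigid frictionless
          supports (in-plane constraints released with reaction ramp-down) and
          the superior platen's axial position is then force-controlled to
          zero net load, so the disc carries no axial compression into the
          cut.  End surfaces stay planar -- the well-conditioned stand-in for
          full detachment.
        * ``"frictionless"``: as above but the axial positions stay fixed
          (the swelling-induced axial compression is retained).
        * ``"free"``: all platen constraints released (free-floating disc,
          3-2-1 gauge).  Faithful to the experiment but traverses
          nearly-unconstrained soft modes where Newton may stall; provided as
          an option.
        """
        if mode not in ("zero_force", "frictionless", "free"):
            raise ValueError(f"unknown platen release mode {mode!r}")
        mesh = self.sys.mesh
        ref = mesh.nodes
        r_out = np.linalg.norm(ref[:, :2], axis=1).max()
        zmid, ztop = 0.5 * ref[:, 2].max(), ref[:, 2].max()
        nA = mesh.nearest_node((-r_out, 0.0, zmid))
        nC = mesh.nearest_node((-0.4 * r_out, 0.0, zmid))
        if mode == "free":
            comps = (0, 1, 2)
            nB = mesh.nearest_node((-r_out, 0.0, ztop))
            gauge = [(nA, (0, 1, 2)), (nB, (0, 1)), (nC, (1,))]
        else:
            comps = (0, 1)
            gauge = [(nA, (0, 1)), (nC, (1,))]

        r = self.sys.residual()
        counter = np.zeros_like(r)
        plat = np.concatenate([mesh.node_sets["inferior"], mesh.node_sets["superior"]])
        for c in comps:
            counter[plat, c] = r[plat, c]
        self.sys.free_nodes(plat, comps)
        for node, gcomps in gauge:
            vals = self.sys.u[node, list(gcomps)][None, :]
            self.sys.set_prescribed(np.array([node]), gcomps, vals)
        self.platens_bonded = False
        self._ramped_release(counter, n_sub)
        if mode == "zero_force":
            self._unload_platen_axial(n_sub)
            self._platen_zero_force = True
        self.stage_history.append(f"release_platens({mode})")

    def _unload_platen_axial(self, n_sub: int = 4) -> None:
        """Drive the superior platen's axial force to zero (rigid planar
        translation as a force-controlled dof), then lock the position in."""
        g = self._platen_g()
        f0 = self.platen_force()
        s, ds = 0.0, 1.0 / max(2, n_sub // 2)
        ds_min = ds / 2**8
        u_saved = self.sys.u.copy()
        while s < 1.0 - 1e-12:
            s_try = min(1.0, s + ds)
            try:
                self.solve(
                    platen_g=g, platen_target=f0 * (1.0 - s_try), max_iter=60
                )
            except ConvergenceError:
                self.sys.u = u_saved.copy()
                ds *= 0.5
                if ds < ds_min:
                    raise
                continue
            s = s_try
            u_saved = self.sys.u.copy()
        sup = self.sys.mesh.node_sets["superior"]
        dz = (
            float(np.mean(self.sys.u[sup, 2] - self._platen_disp(sup)[:, 2]))
            + self.platen.dz
        )
        self._set_platen(dz=dz)

    def simulate_incision(self, n_sub: int = 20, release_platens: bool = True) -> None:
        """Release the tied radial cut faces and re-equilibrate.

        With no stored residual stress (unswollen, fiber-free) the release
        produces no displacement change; a swollen disc opens.
        """
        mesh = self.sys.mesh
        if mesh.cut_released:
            raise ValueError("cut already released")
        if release_platens and self.platens_bonded:
            self.release_platens()
        r = self.sys.residual()
        counter = np.zeros_like(r)
        seam = np.concatenate([mesh.cut_pairs[:, 0], mesh.cut_pairs[:, 1]])
        counter[seam] = r[seam]
        self.sys.mesh = release_cut(mesh)
        self.sys.ties_active = False
        self.sys.invalidate_constraints()
        self._ramped_release(counter, n_sub)
        if self._platen_zero_force:
            # the opening perturbs the (locked-in) axial equilibrium slightly;
            # restore the zero-net-load platen position
            self._unload_platen_axial(n_sub=4)
        self.stage_history.append("incision")

    # ---------------------------------------------------------- observables

    def fiber_field(self) -> FiberField:
        """Per-element fiber stretch/strain/stress for every generation,
        evaluated at element centroids through the relative deformation
        gradient with respect to each family's deposition configuration."""
        sys = self.sys
        if not sys.generations:
            raise ValueError("no fiber generations recorded")
        F_t = sys.centroid_F()
        params = sys.mesh.elem_params()
        n_gen, m = len(sys.generations), sys.mesh.n_elems
        lam = np.zeros((n_gen, m))
        sig = np.zeros((n_gen, m))
        from .materials import fiber_stress_1d

        for gidx, gen in enumerate(sys.generations):
            F_rel = F_t @ np.linalg.inv(gen.F_centroid)
            Fv = np.einsum("mij,mj->mi", F_rel, gen.v_centroid)
            ln = np.linalg.norm(Fv, axis=-1)
            lam[gidx] = np.where(sys.pf.has_fibers, ln, 1.0)
            for e in np.nonzero(sys.pf.has_fibers)[0]:
                sig[gidx, e] = sys.fiber_scale * fiber_stress_1d(
                    max(lam[gidx, e], 1e-9), params[e]
                )
        return FiberField(lambda_n=lam, eps_n=lam - 1.0, sigma_n=sig)

    def opening_gap(self) -> float:
        from .metrics import opening_gap

        return opening_gap(self.sys.mesh, self.sys.u)

    def height_and_bulge(self):
        from .metrics import disc_height_and_bulge

        return disc_height_and_bulge(self.sys.mesh, self.sys.u)


# --------------------------------------------------------------------------
# thin functional wrappers mirroring the protocol-engine operations
# --------------------------------------------------------------------------


def equilibrium_solve(sim: DiscSimulation, **kw) -> dict:
    return sim.solve(**kw)


def swell_to_equilibrium(sim: DiscSimulation, dH: float = 0.0, n_sub: int = 10) -> None:
    sim.swell(dH=dH, n_sub=n_sub)


def run_multigen_deposition(sim: DiscSimulation, omega: float, **kw) -> None:
    sim.run_multigen_deposition(omega, **kw)


def apply_preload(sim: DiscSimulation, load: float, **kw) -> None:
    sim.apply_preload(load, **kw)


def run_test_case(sim: DiscSimulation, case: str, **kw) -> Curve:
    return sim.run_test_case(case, **kw)


def simulate_incision(sim: DiscSimulation, **kw) -> None:
    sim.simulate_incision(**kw)
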