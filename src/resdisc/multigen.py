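"""Multigenerational fiber bookkeeping and kinematics.

Fiber families can be *deposited* at any instant of the loading history; the
deposited family is stress-free in that configuration and its stretch is
thereafter measured through the relative deformation gradient

    F_u(x, t) = F(x, t) F(x, u)^{-1}

where ``u`` is the deposition time and all gradients are taken with respect to
the mesh's time-zero configuration.  The classical (non-multigenerational)
fiber model is the special case of deposition at time zero, F(x, u) = I.

Local material axes follow the hexahedral a/d construction: with standard
isoparametric node ordering, ``a = n2 - n1`` (local 1-direction,
circumferential for disc meshes) and ``d = n5 - n1`` (local axial direction);
``e1 = a/|a|``, ``e3 = a x d / |a x d|``, ``e2 = e3 x e1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import fiber_stress_1d

__all__ = [
    "LocalAxes",
    "Generation",
    "FiberField",
    "local_material_axes",
    "fiber_direction_global",
    "relative_deformation",
    "fiber_stretch",
    "map_direction_to_deposition",
    "compute_fiber_field",
]


@dataclass(frozen=True)
class LocalAxes:
    """Orthonormal right-handed element triad; rows of T_xB are e1, e2, e3."""

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    @property
    def T_xB(self) -> np.ndarray:
        return np.stack([self.e1, self.e2, self.e3], axis=-2)


@dataclass
class Generation:
    """Reference-configuration record for one fiber family.

    ``F_at_deposition`` holds the per-element deformation gradient (relative to
    time zero) at the instant the family was laid down; ``direction`` is the
    per-element *unit* fiber direction in the deposition configuration.
    """

    generation_id: int
    deposition_stage: str
    F_at_deposition: np.ndarray  # (n_elem, 3, 3)
    fiber_angle_sign: int
    direction: np.ndarray  # (n_elem, 3), unit

    def __post_init__(self) -> None:
        if np.any(np.linalg.det(self.F_at_deposition) <= 0):
            raise ValueError("deposition gradients must have positive determinant")
        norms = np.linalg.norm(self.direction, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("deposition directions must be unit vectors")


@dataclass
class FiberField:
    """Per-element, per-generation fiber stretch, strain and stress."""

    lambda_n: np.ndarray  # (n_gen, n_elem)
    eps_n: np.ndarray
    sigma_n: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        n_gen, n_elem = self.lambda_n.shape
        frames = []
        for g in range(n_gen):
            frames.append(
                pd.DataFrame(
                    {
                        "element": np.arange(n_elem),
                        "generation": g,
                        "lambda_n": self.lambda_n[g],
                        "eps_n": self.eps_n[g],
                        "sigma_n": self.sigma_n[g],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def local_material_axes(node_coords: np.ndarray) -> LocalAxes:
    """Element triad from the 8 hex corner positions (standard ordering).

    Vectorized: ``node_coords`` may be ``(8, 3)`` or ``(n, 8, 3)``.
    """
    x = np.asarray(node_coords, dtype=float)
    a = x[..., 1, :] - x[..., 0, :]
    d = x[..., 4, :] - x[..., 0, :]
    cross = np.cross(a, d)
    na = np.linalg.norm(a, axis=-1, keepdims=True)
    nc = np.linalg.norm(cross, axis=-1, keepdims=True)
    if np.any(na == 0) or np.any(nc == 0):
        raise ValueError("degenerate element: a and d are parallel or zero")
    e1 = a / na
    e3 = cross / nc
    e2 = np.cross(e3, e1)
    return LocalAxes(e1=e1, e2=e2, e3=e3)


def fiber_direction_global(axes: LocalAxes, theta: float, sign: int) -> np.ndarray:
    """Global unit fiber direction T_xB^T (cos(s*theta), sin(s*theta), 0).

    ``theta`` in degrees; ``sign`` selects which of the +/-theta pair.
    """
    t = np.deg2rad(sign * theta)
    v_local = np.array([np.cos(t), np.sin(t), 0.0])
    # rows of T_xB are e1,e2,e3 => global v = v1*e1 + v2*e2 + v3*e3
    return (
        v_local[0] * axes.e1 + v_local[1] * axes.e2 + v_local[2] * axes.e3
    )


def relative_deformation(F_t: np.ndarray, F_u: np.ndarray) -> np.ndarray:
    """F(x,t) F(x,u)^{-1}: deformation at t relative to the deposition time u."""
    F_u = np.asarray(F_u, dtype=float)
    if np.any(np.linalg.det(F_u) <= 0):
        raise ValueError("singular or inverted deposition gradient")
    return np.asarray(F_t, dtype=float) @ np.linalg.inv(F_u)


def fiber_stretch(F_rel: np.ndarray, v: np.ndarray) -> np.ndarray:
    """lambda_n = sqrt(v . C v) with C = F_rel^T F_rel and unit v."""
    Fv = np.einsum("...ij,...j->...i", np.asarray(F_rel, float), np.asarray(v, float))
    return np.linalg.norm(Fv, axis=-1)


def map_direction_to_deposition(F_u: np.ndarray, v_time0: np.ndarray) -> np.ndarray:
    """Push the time-zero direction to the deposition configuration (unit)."""
    F_u = np.asarray(F_u, dtype=float)
    if np.any(np.linalg.det(F_u) <= 0):
        raise ValueError("singular or inverted deposition gradient")
    v = np.einsum("...ij,...j->...i", F_u, np.asarray(v_time0, float))
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def compute_fiber_field(F_t, generations, elem_params) -> FiberField:
    """Per-element fiber stretch/strain/stress for every generation.

    Parameters
    ----------
    F_t : (n_elem, 3, 3) current per-element deformation gradients (vs time 0).
    generations : list of Generation (must be non-empty).
    elem_params : sequence of MaterialParams, one per element (fiber-free
        regions yield zero stress and unit stretch placeholders are *not*
        masked -- lambda is still reported from kinematics, stress is 0).
    """
    if not generations:
        raise ValueError("no generation records supplied")
    F_t = np.asarray(F_t, dtype=float)
    n_elem = F_t.shape[0]
    lam = np.zeros((len(generations), n_elem))
    sig = np.zeros_like(lam)
    has_fibers = np.array([p.has_fibers for p in elem_params], dtype=bool)
    for g, gen in enumerate(generations):
        if gen.F_at_deposition.shape[0] != n_elem:
            raise ValueError("generation record does not cover every element")
        F_rel = relative_deformation(F_t, gen.F_at_deposition)
        lam[g] = fiber_stretch(F_rel, gen.direction)
        for e in range(n_elem):
            if has_fibers[e]:
                sig[g, e] = fiber_stress_1d(lam[g, e], elem_params[e])
    return FiberField(lambda_n=lam, eps_n=lam - 1.0, sigma_n=sig)
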