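"""Validation and outcome metrics.

* NMSE — model-vs-experiment mean square error normalized by the squared
  deviation of the 95% confidence band from the experimental mean; 0 is a
  perfect match, values above 1 put the model outside the confidence band.
* Opening gap W_i — distance between the cut faces after the radial incision,
  measured between the outer annulus edges at mid-height.
* Disc height (median superior-inferior distance on the mid-coronal plane)
  and lateral bulge beyond the platen edge.
* Anatomic transforms — tensor fields rotated into per-element (radial,
  circumferential, axial) axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import Mesh

__all__ = [
    "Curve",
    "GeometryMetrics",
    "nmse",
    "opening_gap",
    "disc_height_and_bulge",
    "anatomic_transform",
    "preload_from_lengths",
]


@dataclass
class Curve:
    """Sampled scalar response with optional experimental mean/CI companions."""

    x: np.ndarray
    y_model: np.ndarray
    y_expmean: Optional[np.ndarray] = None
    y_ci: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y_model = np.asarray(self.y_model, dtype=float)
        if self.x.shape != self.y_model.shape:
            raise ValueError("x and y_model must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        for name in ("y_expmean", "y_ci"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.x.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def to_dataframe(self):
        import pandas as pd

        data = {"x": self.x, "y_model": self.y_model}
        if self.y_expmean is not None:
            data["y_expmean"] = self.y_expmean
        if self.y_ci is not None:
            data["y_ci"] = self.y_ci
        return pd.DataFrame(data)


@dataclass
class GeometryMetrics:
    median_height: float
    bulge_left: float
    bulge_right: float
    opening_gap: Optional[float] = None


def nmse(curve: Curve, model_x: Optional[np.ndarray] = None) -> float:
    """Normalized mean square error of a model curve against experiment.

    ``sum((Y_model - Y_expmean)^2) / sum((Y_95CI - Y_expmean)^2)`` over the
    experimental abscissa.  If the model was sampled on a different abscissa,
    pass it as ``model_x`` and the model curve is linearly interpolated onto
    the experimental one first.
    """
    if curve.y_expmean is None or curve.y_ci is None:
        raise ValueError("experimental mean and CI bound are required")
    y_model = curve.y_model
    if model_x is not None:
        y_model = np.interp(curve.x, np.asarray(model_x, float), y_model)
    denom = float(np.sum((curve.y_ci - curve.y_expmean) ** 2))
    if denom == 0.0:
        raise ValueError("degenerate confidence band (zero width)")
    return float(np.sum((y_model - curve.y_expmean) ** 2) / denom)


def _cut_edge_points(mesh: Mesh, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = mesh.nodes
    pairs = mesh.cut_pairs
    r = np.linalg.norm(ref[pairs[:, 0], :2], axis=1)
    zmid = 0.5 * (ref[:, 2].min() + ref[:, 2].max())
    outer = r >= r.max() - 1e-9
    cand = pairs[outer]
    dz = np.abs(ref[cand[:, 0], 2] - zmid)
    sel = cand[dz <= dz.min() + 1e-9]
    xa = (ref[sel[:, 0]] + u[sel[:, 0]]).mean(axis=0)
    xb = (ref[sel[:, 1]] + u[sel[:, 1]]).mean(axis=0)
    return xa, xb


def opening_gap(mesh: Mesh, u: np.ndarray) -> float:
    """Opening gap W_i (mm): distance between the cut-face outer edges at
    mid-height after the incision has been released and re-equilibrated."""
    if not mesh.cut_released:
        raise ValueError("cut has not been released")
    xa, xb = _cut_edge_points(mesh, u)
    return float(np.linalg.norm(xa - xb))


def disc_height_and_bulge(mesh: Mesh, u: np.ndarray) -> GeometryMetrics:
    """Median disc height and left/right lateral bulge.

    Height: median distance between paired superior/inferior surface points
    near the mid-coronal (y = 0) plane.  Bulge: lateral extrusion of the disc
    boundary beyond the deformed platen edge, per side.
    """
    ref = mesh.nodes
    cur = ref + u
    sup = mesh.node_sets["superior"]
    inf = mesh.node_sets["inferior"]
    # pair superior/inferior nodes by reference (x, y); structured meshes
    # guarantee exact column alignment
    key_s = np.round(ref[sup, :2], 6)
    key_i = np.round(ref[inf, :2], 6)
    order_s = np.lexsort((key_s[:, 1], key_s[:, 0]))
    order_i = np.lexsort((key_i[:, 1], key_i[:, 0]))
    ps, pi = sup[order_s], inf[order_i]
    ytol = 0.15 * (ref[:, 1].max() - ref[:, 1].min())
    mid = np.abs(ref[ps, 1]) <= ytol
    heights = cur[ps[mid], 2] - cur[pi[mid], 2]
    median_height = float(np.median(heights))

    bulges = {}
    for side, sgn in (("right", +1), ("left", -1)):
        lateral = sgn * ref[:, 0] > 0.5 * ref[:, 0].max()
        platen_edge = sgn * cur[sup, 0].max() if sgn > 0 else -cur[sup, 0].min()
        extent = cur[lateral, 0].max() if sgn > 0 else -cur[lateral, 0].min()
        bulges[side] = float(max(extent - platen_edge, 0.0))
    return GeometryMetrics(
        median_height=median_height,
        bulge_left=bulges["left"],
        bulge_right=bulges["right"],
    )


def anatomic_transform(tensors: np.ndarray, mesh: Mesh) -> np.ndarray:
    """Rotate per-element tensors into (radial, circumferential, axial) axes.

    Components of the output: index 0 radial, 1 circumferential, 2 axial.
    Elements on the axis (degenerate radial direction) fall back to global
    axes with a warning.  Invariants (trace, determinant) are preserved.
    """
    tensors = np.asarray(tensors, dtype=float)
    cents = mesh.centroids()
    r = np.linalg.norm(cents[:, :2], axis=1)
    out = np.empty_like(tensors)
    degen = r < 1e-9
    if np.any(degen):
        warnings.warn("elements on the axis: using global axes for them")
    er = np.zeros((len(cents), 3))
    er[~degen, 0] = cents[~degen, 0] / r[~degen]
    er[~degen, 1] = cents[~degen, 1] / r[~degen]
    er[degen] = (1.0, 0.0, 0.0)
    ez = np.tile((0.0, 0.0, 1.0), (len(cents), 1))
    ec = np.cross(ez, er)
    Q = np.stack([er, ec, ez], axis=1)  # rows: radial, circ, axial
    return Q @ tensors @ np.swapaxes(Q, -1, -2)


def preload_from_lengths(L_rl: float, L_ap: float) -> tuple[float, float]:
    """Disc cross-section area estimate and physiological preload.

    ``A = 0.84 L_rl L_ap`` (mm^2); ``preload = 0.2 MPa * A * 1.5`` (N), the
    load producing physiologically relevant nucleus pressurization.
    """
    if L_rl < 0 or L_ap < 0:
        raise ValueError("lengths must be nonnegative")
    A = 0.84 * L_rl * L_ap
    return A, 0.2 * A * 1.5
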