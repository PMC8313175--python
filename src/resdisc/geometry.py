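"""Parameterized disc meshes: bovine cylinder and human-like elliptical disc.

Both shapes share one solid hexahedral topology: a central Cartesian
"butterfly" block mapped smoothly onto a disc core (no axis degeneracy, no
hole), surrounded by concentric element rings, extruded axially.  Region
labels are assigned ring-by-ring from the nucleus outward:

    NP (core + inner rings) -> NPtrans (1 ring) -> IAF -> AFtrans (1 ring) -> OAF

A radial cut seam lies along the positive x axis: every node on that
half-plane (except the axis itself) is duplicated and the duplicates are tied
until the incision releases them, after which the disc can open like an
opening-angle specimen while remaining connected through the negative-x half.

The human shape is the same topology with the cross-section scaled to an
ellipse (left-right semi-axis ``semi_x``, anterior-posterior ``semi_y``) and
an optional initial outward "bulge" of the lateral boundary at mid-height.

Coordinates: z axial (superior +), x left-right, y anterior-posterior; mm.
Standard isoparametric hex node ordering; for annulus elements the local
1-direction (a = n2 - n1) is circumferential and the local axial direction
(d = n5 - n1) is +z, as the fiber-angle convention requires.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .materials import MaterialParams
from .multigen import LocalAxes, local_material_axes

__all__ = [
    "GeometrySpec",
    "Mesh",
    "build_bovine_cylinder",
    "build_human_parametric",
    "assign_region_params",
    "release_cut",
    "retie_cut",
]


@dataclass
class GeometrySpec:
    """Parameterized disc geometry.

    ``shape`` is ``"bovine_cylinder"`` or ``"human_parametric"``.  For the
    cylinder, ``outer_radius`` is the section radius; for the human shape the
    section is an ellipse with semi-axes ``semi_x`` (left-right) and ``semi_y``
    (anterior-posterior) and the builder scales the circular section.
    ``np_fraction`` is the nucleus fraction of the radius.  AFtrans and
    NPtrans are always exactly one element thick, ``trans_thickness`` mm each.
    ``n_theta`` must be a multiple of 8 (butterfly core), ``n_np`` counts the
    annular NP rings outside the core block.
    """

    shape: str = "bovine_cylinder"
    height: float = 7.0
    outer_radius: float = 10.0
    semi_x: float = 20.0
    semi_y: float = 13.4
    np_fraction: float = 0.5
    core_fraction: float = 0.45  # core-block radius as fraction of NP radius
    trans_thickness: float = 0.5
    n_theta: int = 24
    n_axial: int = 3
    n_np: int = 2
    n_iaf: int = 3
    n_oaf: int = 3
    bulge: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("bovine_cylinder", "human_parametric"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if min(self.height, self.outer_radius, self.trans_thickness) <= 0:
            raise ValueError("dimensions must be positive")
        if not (0 < self.np_fraction < 1):
            raise ValueError("np_fraction must lie in (0, 1)")
        if not (0 < self.core_fraction < 1):
            raise ValueError("core_fraction must lie in (0, 1)")
        if min(self.n_axial, self.n_np, self.n_iaf, self.n_oaf) < 1:
            raise ValueError("mesh resolution counts must be >= 1")
        if self.n_theta < 16 or self.n_theta % 8 != 0:
            raise ValueError("n_theta must be a multiple of 8, at least 16")
        r_np = self.np_fraction * self.outer_radius
        if r_np - self.trans_thickness / 2 <= self.core_fraction * r_np:
            raise ValueError("NP annulus too thin for the requested core block")
        af_span = self.outer_radius - r_np - 1.5 * self.trans_thickness
        if af_span <= 0:
            raise ValueError(
                "resolution/thickness leaves no room for IAF/OAF rings "
                "while honoring the 1-element transitional layers"
            )

    @property
    def core_radius(self) -> float:
        return self.core_fraction * self.np_fraction * self.outer_radius

    def ring_radii_and_regions(self) -> tuple[np.ndarray, list[str]]:
        """Annular nodal radii (core boundary outward) and ring region labels."""
        r_np_out = self.np_fraction * self.outer_radius - self.trans_thickness / 2
        radii = [self.core_radius]
        regions: list[str] = []
        radii.extend(np.linspace(self.core_radius, r_np_out, self.n_np + 1)[1:])
        regions.extend(["NP"] * self.n_np)
        radii.append(r_np_out + self.trans_thickness)
        regions.append("NPtrans")
        af_in = radii[-1]
        af_span = self.outer_radius - af_in - self.trans_thickness
        iaf_span = af_span * self.n_iaf / (self.n_iaf + self.n_oaf)
        radii.extend(np.linspace(af_in, af_in + iaf_span, self.n_iaf + 1)[1:])
        regions.extend(["IAF"] * self.n_iaf)
        radii.append(af_in + iaf_span + self.trans_thickness)
        regions.append("AFtrans")
        radii.extend(np.linspace(radii[-1], self.outer_radius, self.n_oaf + 1)[1:])
        regions.extend(["OAF"] * self.n_oaf)
        return np.asarray(radii), regions

    def expected_element_count(self) -> int:
        s = self.n_theta // 8
        _, regions = self.ring_radii_and_regions()
        return self.n_axial * ((2 * s) ** 2 + len(regions) * self.n_theta)


@dataclass
class Mesh:
    """Hexahedral disc mesh with region labels and the radial cut seam."""

    nodes: np.ndarray  # (n_nodes, 3) reference coordinates, mm
    elems: np.ndarray  # (n_elem, 8) connectivity
    region: np.ndarray  # (n_elem,) region label strings
    node_sets: dict  # 'superior', 'inferior', 'outer', 'cut_a', 'cut_b'
    cut_pairs: np.ndarray  # (k, 2) tied node pairs (a, b), coincident
    spec: Optional[GeometrySpec] = None
    cut_released: bool = False
    params: Optional[dict] = None  # region label -> MaterialParams
    _axes: Optional[LocalAxes] = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elems]  # (n_elem, 8, 3)

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def local_axes(self) -> LocalAxes:
        if self._axes is None:
            self._axes = local_material_axes(self.element_coords())
        return self._axes

    def elem_params(self) -> list[MaterialParams]:
        if self.params is None:
            raise ValueError(
                "material parameters not assigned; call assign_region_params"
            )
        return [self.params[r] for r in self.region]

    def scaled_jacobians(self) -> np.ndarray:
        """Scaled Jacobian at element centroids (mesh-quality measure)."""
        from .fem import centroid_jacobians

        return centroid_jacobians(self)

    def nearest_node(self, point) -> int:
        return int(np.argmin(np.linalg.norm(self.nodes - np.asarray(point), axis=1)))


def _build_solid_disc(spec: GeometrySpec, xy_scale: tuple[float, float]) -> Mesh:
    s = spec.n_theta // 8
    nt, nz = spec.n_theta, spec.n_axial
    a = spec.core_radius
    radii, ring_regions = spec.ring_radii_and_regions()
    n_ring = len(ring_regions)
    zs = np.linspace(0.0, spec.height, nz + 1)

    # --- 2-D node layout -------------------------------------------------
    pts2d: list[tuple[float, float]] = []

    def add_pt(x: float, y: float) -> int:
        pts2d.append((x, y))
        return len(pts2d) - 1

    # core block: elliptic square-to-disc map; boundary lands on r = a
    core_id = {}
    core_b = {}  # B-side duplicates along the cut row (j = s, i > s)
    for i in range(2 * s + 1):
        xi = (i - s) / s
        for j in range(2 * s + 1):
            eta = (j - s) / s
            x = a * xi * np.sqrt(1.0 - 0.5 * eta * eta)
            y = a * eta * np.sqrt(1.0 - 0.5 * xi * xi)
            core_id[i, j] = add_pt(x, y)
            if j == s and i > s:
                core_b[i] = add_pt(x, y)

    # boundary walk, counterclockwise from (2s, s) at theta = 0
    walk: list[tuple[int, int]] = []
    walk += [(2 * s, j) for j in range(s, 2 * s + 1)]
    walk += [(i, 2 * s) for i in range(2 * s - 1, -1, -1)]
    walk += [(0, j) for j in range(2 * s - 1, -1, -1)]
    walk += [(i, 0) for i in range(1, 2 * s + 1)]
    walk += [(2 * s, j) for j in range(1, s)]
    assert len(walk) == nt

    def bid(k: int) -> int:
        """Core-boundary node at angular position k (0..nt); nt is the B-side
        duplicate of position 0 (both on the cut)."""
        if k == nt:
            return core_b[2 * s]
        return core_id[walk[k]]

    thetas = np.empty(nt + 1)
    for k in range(nt):
        x, y = pts2d[core_id[walk[k]]]
        t = np.arctan2(y, x)
        thetas[k] = t if t >= 0 or k == 0 else t + 2 * np.pi
    thetas[0] = 0.0
    thetas[nt] = 2.0 * np.pi

    # annular rings (ring 0 is the core boundary itself)
    ann_id = {}
    for ir in range(1, n_ring + 1):
        r = radii[ir]
        for k in range(nt + 1):
            ann_id[ir, k] = add_pt(r * np.cos(thetas[k]), r * np.sin(thetas[k]))

    def ring_node(ir: int, k: int) -> int:
        return bid(k) if ir == 0 else ann_id[ir, k]

    pts2d_arr = np.asarray(pts2d)
    n2d = len(pts2d)

    # --- extrude ---------------------------------------------------------
    def nid(p2d: int, kz: int) -> int:
        return p2d * (nz + 1) + kz

    sx, sy = xy_scale
    nodes = np.empty((n2d * (nz + 1), 3))
    for p in range(n2d):
        x, y = pts2d_arr[p]
        for kz, z in enumerate(zs):
            nodes[nid(p, kz)] = (x * sx, y * sy, z)

    if spec.bulge > 0.0:
        r_ref = np.linalg.norm(nodes[:, :2], axis=1)
        r_out_eff = r_ref.max()
        with np.errstate(invalid="ignore", divide="ignore"):
            dirs = np.where(
                r_ref[:, None] > 1e-12, nodes[:, :2] / np.clip(r_ref[:, None], 1e-12, None), 0.0
            )
        w = (r_ref / r_out_eff) ** 4 * spec.bulge * np.sin(
            np.pi * nodes[:, 2] / spec.height
        )
        nodes[:, :2] += w[:, None] * dirs

    # --- elements --------------------------------------------------------
    def core_node(ii: int, jj: int, above: bool) -> int:
        if jj == s and ii > s and not above:
            return core_b[ii]
        return core_id[ii, jj]

    elems = []
    region = []
    for i in range(2 * s):
        for j in range(2 * s):
            above = j >= s
            q = [
                core_node(i, j, above),
                core_node(i + 1, j, above),
                core_node(i + 1, j + 1, above),
                core_node(i, j + 1, above),
            ]
            for kz in range(nz):
                elems.append(
                    [nid(p, kz) for p in q] + [nid(p, kz + 1) for p in q]
                )
                region.append("NP")
    for q in range(n_ring):
        for k in range(nt):
            base = [
                ring_node(q + 1, k),
                ring_node(q + 1, k + 1),
                ring_node(q, k + 1),
                ring_node(q, k),
            ]
            for kz in range(nz):
                elems.append(
                    [nid(p, kz) for p in base] + [nid(p, kz + 1) for p in base]
                )
                region.append(ring_regions[q])
    elems = np.asarray(elems, dtype=np.int64)
    region = np.asarray(region)

    # --- cut pairs and node sets ----------------------------------------
    pairs2d = [(core_id[i, s], core_b[i]) for i in range(s + 1, 2 * s + 1)]
    pairs2d += [(ann_id[ir, 0], ann_id[ir, nt]) for ir in range(1, n_ring + 1)]
    cut_pairs = np.array(
        [
            [nid(pa, kz), nid(pb, kz)]
            for (pa, pb) in pairs2d
            for kz in range(nz + 1)
        ],
        dtype=np.int64,
    )
    all2d = np.arange(n2d)
    node_sets = {
        "superior": all2d * (nz + 1) + nz,
        "inferior": all2d * (nz + 1),
        "outer": np.array(
            [nid(ann_id[n_ring, k], kz) for k in range(nt + 1) for kz in range(nz + 1)]
        ),
        "cut_a": cut_pairs[:, 0].copy(),
        "cut_b": cut_pairs[:, 1].copy(),
    }
    return Mesh(
        nodes=nodes,
        elems=elems,
        region=region,
        node_sets=node_sets,
        cut_pairs=cut_pairs,
        spec=spec,
    )


def build_bovine_cylinder(spec: Optional[GeometrySpec] = None) -> Mesh:
    """Solid concentric-region cylinder with a tied radial cut seam."""
    if spec is None:
        spec = GeometrySpec(shape="bovine_cylinder")
    if spec.shape != "bovine_cylinder":
        raise ValueError("spec.shape must be 'bovine_cylinder'")
    return _build_solid_disc(spec, (1.0, 1.0))


def build_human_parametric(spec: Optional[GeometrySpec] = None) -> Mesh:
    """Layered elliptical disc; circular limit coincides with the cylinder."""
    if spec is None:
        spec = GeometrySpec(
            shape="human_parametric", height=11.0, n_axial=4, bulge=0.5
        )
    if spec.shape != "human_parametric":
        raise ValueError("spec.shape must be 'human_parametric'")
    scale = (spec.semi_x / spec.outer_radius, spec.semi_y / spec.outer_radius)
    return _build_solid_disc(spec, scale)


def assign_region_params(mesh: Mesh, table: dict[str, MaterialParams]) -> Mesh:
    """Attach a region -> MaterialParams table; every present label must be covered."""
    missing = sorted(set(mesh.region) - set(table))
    if missing:
        raise ValueError(f"material table missing regions: {missing}")
    mesh.params = dict(table)
    return mesh


def release_cut(mesh: Mesh) -> Mesh:
    """Free the tied cut-face node pairs (returns a shallow copy with the flag set)."""
    if mesh.cut_pairs is None or len(mesh.cut_pairs) == 0:
        raise ValueError("mesh has no cut plane defined")
    out = copy.copy(mesh)
    out.cut_released = True
    return out


def retie_cut(mesh: Mesh) -> Mesh:
    """Re-tie the cut faces (inverse of :func:`release_cut`)."""
    out = copy.copy(mesh)
    out.cut_released = False
    return out
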