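"""Run configuration: YAML schema, loading, validation, and result output.

A run config describes geometry, per-region material parameters, bath
environment, protocol mode (swelling-only or multigeneration with Omega and
dH), solver tolerances and output paths.  The packaged defaults reproduce the
default material table verbatim; a config file only needs to override what it
changes.  Saving a run emits curves as CSV, metrics as JSON, field snapshots
as legacy-ASCII VTK, and an echo of the fully-resolved config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .geometry import GeometrySpec, Mesh
from .materials import Environment, InvalidParameterError, MaterialParams
from .metrics import Curve
from .presets import default_environment, default_material_table

__all__ = ["RunConfig", "load_config", "save_results", "write_vtk", "config_to_dict"]


_MAT_FIELDS = (
    "E_m",
    "nu",
    "beta_m",
    "k0",
    "M",
    "c0F",
    "E_f",
    "lambda0",
    "theta",
    "beta_f",
    "phi0_s",
)


@dataclasses.dataclass
class RunConfig:
    geometry: GeometrySpec
    materials: dict  # region label -> MaterialParams
    environment: Environment
    mode: str = "swelling_only"
    omega: float = 3.0
    dH: float = 0.0
    preload: float = 0.0
    protocol: str = "incision"
    tol_rel: float = 1e-8
    tol_abs: float = 1e-9
    max_iter: int = 25
    n_swell_sub: int = 10
    out_dir: Optional[str] = None
    seed: int = 0  # used only by fixture-noise generation

    def __post_init__(self) -> None:
        if self.mode not in ("swelling_only", "multigen"):
            raise InvalidParameterError("mode must be swelling_only or multigen")
        if self.mode == "multigen" and self.omega is None:
            raise InvalidParameterError("multigen mode requires omega")

    def newton_kw(self) -> dict:
        return dict(tol_rel=self.tol_rel, tol_abs=self.tol_abs, max_iter=self.max_iter)


def _materials_from_dict(overrides: Optional[dict]) -> dict:
    table = default_material_table()
    if not overrides:
        return table
    for region, fields in overrides.items():
        if region not in table:
            raise InvalidParameterError(f"materials.{region}: unknown region")
        base = dataclasses.asdict(table[region])
        for key, val in (fields or {}).items():
            if key not in _MAT_FIELDS:
                raise InvalidParameterError(f"materials.{region}.{key}: unknown field")
            base[key] = val
        try:
            table[region] = MaterialParams(**base)
        except (InvalidParameterError, ValueError) as exc:
            raise InvalidParameterError(f"materials.{region}: {exc}") from exc
    return table


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a YAML config file (or an equivalent dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    try:
        geo = GeometrySpec(**(raw.get("geometry") or {}))
    except (TypeError, ValueError) as exc:
        raise InvalidParameterError(f"geometry: {exc}") from exc
    mats = _materials_from_dict(raw.get("materials"))
    try:
        env = Environment(**(raw.get("environment") or {}))
    except (TypeError, InvalidParameterError) as exc:
        raise InvalidParameterError(f"environment: {exc}") from exc
    run = raw.get("run") or {}
    known = {f.name for f in dataclasses.fields(RunConfig)} - {
        "geometry",
        "materials",
        "environment",
    }
    unknown = set(run) - known
    if unknown:
        raise InvalidParameterError(f"run: unknown keys {sorted(unknown)}")
    return RunConfig(geometry=geo, materials=mats, environment=env, **run)


def config_to_dict(cfg: RunConfig) -> dict:
    mats = {}
    for region, p in cfg.materials.items():
        mats[region] = {k: getattr(p, k) for k in _MAT_FIELDS}
    out = {
        "geometry": dataclasses.asdict(cfg.geometry),
        "materials": mats,
        "environment": {
            "bath_osmolarity": cfg.environment.bath_osmolarity,
            "temperature": cfg.environment.temperature,
            "osmotic_coefficient": cfg.environment.osmotic_coefficient,
        },
        "run": {
            f.name: getattr(cfg, f.name)
            for f in dataclasses.fields(RunConfig)
            if f.name not in ("geometry", "materials", "environment")
        },
    }
    return out


def save_results(
    out_dir,
    cfg: RunConfig,
    curves: Optional[dict] = None,
    metrics: Optional[dict] = None,
    mesh: Optional[Mesh] = None,
    u: Optional[np.ndarray] = None,
    fields: Optional[dict] = None,
) -> Path:
    """Write curves (CSV), metrics (JSON), fields (VTK) and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
    for name, curve in (curves or {}).items():
        curve.to_dataframe().to_csv(out / f"{name}.csv", index=False)
    if metrics is not None:
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, default=float)
    if mesh is not None:
        write_vtk(out / "fields.vtk", mesh, u=u, cell_fields=fields)
    return out


def write_vtk(path, mesh: Mesh, u=None, cell_fields: Optional[dict] = None) -> None:
    """Minimal legacy-ASCII VTK unstructured-grid writer (hexahedra only).

    Hand-rolled because the deployment environment carries no VTK bindings;
    output loads in ParaView/VisIt.  ``u`` is written as a point vector field;
    ``cell_fields`` maps names to per-element scalar arrays.
    """
    mesh_pts = mesh.nodes if u is None else mesh.nodes + u
    lines = [
        "# vtk DataFile Version 3.0",
        "resdisc field output",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh_pts]
    lines.append(f"CELLS {mesh.n_elems} {mesh.n_elems * 9}")
    lines += ["8 " + " ".join(str(i) for i in e) for e in mesh.elems]
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines += ["12"] * mesh.n_elems
    if u is not None:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement double")
        lines += [" ".join(f"{v:.9g}" for v in p) for p in u]
    if cell_fields:
        lines.append(f"CELL_DATA {mesh.n_elems}")
        for name, arr in cell_fields.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{float(v):.9g}" for v in np.asarray(arr).ravel()]
    Path(path).write_text("\n".join(lines) + "\n")
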