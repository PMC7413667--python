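"""File I/O: meshes (legacy-ASCII VTK polydata, PLY), manifests, tables.

Mesh roles are resolved either from the filename convention
``<cell_id>_cell.vtk`` / ``<cell_id>_mito.vtk`` / ``<cell_id>_vac.vtk`` /
``<cell_id>_nuc.vtk`` or from an explicit YAML manifest binding files to
cells and roles. Units are µm throughout; a reader converts if the caller
declares nm coordinates.
"""

from __future__ import annotations


import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import CellGeometry, MeshValidationError, SurfaceMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "load_manifest",
    "write_manifest",
    "read_trajectories",
    "write_trajectories",
    "write_volume_summaries",
]

_SUFFIX_ROLE = {
    "cell": "cell",
    "mito": "mitochondrion",
    "vac": "vacuole",
    "nuc": "nucleus",
}

VOLUME_SUMMARY_COLUMNS = [
    "cell_id",
    "cell_volume_um3",
    "mito_volume_um3",
    "mito_surface_um2",
    "vacuole_volume_um3",
    "mito_volume_fraction",
    "effective_mito_volume_fraction",
]

TRAJECTORY_COLUMNS = ["cell_id", "track_id", "t_s", "x_um", "y_um", "z_um"]


def _role_from_name(path: Path) -> str | None:
    m = re.search(r"_(cell|mito|vac|nuc)(?:\d*)$", path.stem)
    return _SUFFIX_ROLE[m.group(1)] if m else None


def read_mesh(path, label: str | None = None, units: str = "um") -> SurfaceMesh:
    """Read a triangulated mesh from legacy-ASCII VTK polydata or PLY."""
    path = Path(path)
    if label is None:
        label = _role_from_name(path) or "cell"
    if path.suffix.lower() == ".vtk":
        vertices, faces = _read_vtk_ascii(path)
    elif path.suffix.lower() == ".ply":
        import trimesh

        m = trimesh.load(str(path), file_type="ply", process=False)
        vertices, faces = np.asarray(m.vertices), np.asarray(m.faces)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")
    if units == "nm":
        vertices = vertices / 1000.0
    elif units != "um":
        raise ValueError("units must be 'um' or 'nm'")
    return SurfaceMesh(vertices, faces, label=label)


def write_mesh(mesh: SurfaceMesh, path) -> Path:
    """Write a mesh as legacy-ASCII VTK polydata or ASCII PLY (by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        _write_vtk_ascii(mesh, path)
    elif path.suffix.lower() == ".ply":
        mesh.as_trimesh().export(str(path), file_type="ply", encoding="ascii")
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")
    return path


def _read_vtk_ascii(path: Path):
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise MeshValidationError(f"{path}: not a legacy VTK file")
    # tokenize once; section keywords carry counts
    words: list[str] = []
    for ln in lines:
        words.extend(ln.split())
    k = 0
    verts = faces = None
    while k < len(words):
        w = words[k].upper()
        if w == "POINTS":
            n_points = int(words[k + 1])
            data = np.array(words[k + 3 : k + 3 + 3 * n_points], dtype=float)
            verts = data.reshape(n_points, 3)
            k += 3 + 3 * n_points
        elif w == "POLYGONS":
            n_polys = int(words[k + 1])
            total = int(words[k + 2])
            data = np.array(words[k + 3 : k + 3 + total], dtype=np.int64)
            k += 3 + total
            faces = []
            j = 0
            for _ in range(n_polys):
                sz = data[j]
                poly = data[j + 1 : j + 1 + sz]
                if sz == 3:
                    faces.append(poly)
                else:  # fan-triangulate larger polygons
                    for t in range(1, sz - 1):
                        faces.append(np.array([poly[0], poly[t], poly[t + 1]]))
                j += 1 + sz
            faces = np.array(faces, dtype=np.int64)
        else:
            k += 1
    if verts is None or faces is None:
        raise MeshValidationError(f"{path}: missing POINTS or POLYGONS section")
    return verts, faces


def _write_vtk_ascii(mesh: SurfaceMesh, path: Path) -> None:
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"mitoloc {mesh.label} surface\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def write_manifest(geoms, out_dir, mesh_format: str = "vtk") -> Path:
    """Write per-cell meshes plus a YAML manifest binding files to roles."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = []
    for geom in geoms:
        entry: dict = {"cell_id": geom.cell_id}
        cid = geom.cell_id
        entry["cell"] = write_mesh(geom.cell, out_dir / f"{cid}_cell.{mesh_format}").name
        entry["mitochondria"] = [
            write_mesh(m, out_dir / f"{cid}_mito{i}.{mesh_format}").name
            for i, m in enumerate(geom.mitochondria)
        ]
        if geom.vacuoles:
            entry["vacuoles"] = [
                write_mesh(m, out_dir / f"{cid}_vac{i}.{mesh_format}").name
                for i, m in enumerate(geom.vacuoles)
            ]
        if geom.nucleus is not None:
            entry["nucleus"] = write_mesh(
                geom.nucleus, out_dir / f"{cid}_nuc.{mesh_format}"
            ).name
        cells.append(entry)
    manifest = out_dir / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"cells": cells}, fh, sort_keys=False)
    return manifest


def load_manifest(manifest_path) -> list[CellGeometry]:
    """Load CellGeometry objects from a YAML manifest written by this module."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        spec = yaml.safe_load(fh)
    base = manifest_path.parent
    geoms = []
    for entry in spec["cells"]:
        geoms.append(
            CellGeometry(
                cell=read_mesh(base / entry["cell"], label="cell"),
                mitochondria=[
                    read_mesh(base / p, label="mitochondrion")
                    for p in entry.get("mitochondria", [])
                ],
                vacuoles=[
                    read_mesh(base / p, label="vacuole")
                    for p in entry.get("vacuoles", [])
                ],
                nucleus=(
                    read_mesh(base / entry["nucleus"], label="nucleus")
                    if entry.get("nucleus")
                    else None
                ),
                cell_id=str(entry["cell_id"]),
            )
        )
    return geoms


def read_trajectories(path) -> pd.DataFrame:
    """Read a trajectory table ``cell_id,track_id,t_s,x_um,y_um,z_um``."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    return df[TRAJECTORY_COLUMNS].astype(
        {"cell_id": str, "track_id": np.int64, "t_s": float}
    )


def write_trajectories(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def write_volume_summaries(summaries, path) -> Path:
    """Write VolumeSummary objects as the canonical per-cell CSV."""
    rows = [s.as_row() for s in summaries]
    df = pd.DataFrame(rows, columns=VOLUME_SUMMARY_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    return path
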