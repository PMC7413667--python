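"""Triangulated-mesh geometry: volumes, areas, and volume fractions.

The central quantity of the whole analysis is the **mitochondrial volume
fraction** f = V_mito / V_cell of a budding-yeast cell, and its
vacuole-corrected variant f_eff = V_mito / (V_cell - V_vacuole [- V_nucleus])
that divides by the *accessible* cytosolic volume instead of the whole cell.
Cells growing on a respiratory carbon source expand their mitochondrial
network, roughly doubling f relative to fermentative growth, and f is the
geometric driver of untargeted mRNA-mitochondria encounters.

Meshes are closed, consistently oriented triangle surfaces in µm (as produced
by MitoGraph-style reconstructions of fluorescence images). Volumes come from
the divergence theorem; a mesh with open edges, non-manifold edges, or more
than 1% of faces wound against the majority orientation is rejected with an
error naming the defect, while a globally inverted mesh is accepted (absolute
value of the signed volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import spatial

__all__ = [
    "SurfaceMesh",
    "CellGeometry",
    "VolumeSummary",
    "MeshValidationError",
    "mesh_volume",
    "mesh_surface_area",
    "volume_summary",
    "ellipse_depth_volume",
]

VALID_LABELS = ("cell", "mitochondrion", "vacuole", "nucleus")


class MeshValidationError(ValueError):
    """A mesh violates the requirements of the requested operation."""


@dataclass
class SurfaceMesh:
    """A triangulated surface in µm.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    label : role of the surface ("cell", "mitochondrion", "vacuole",
        "nucleus")
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = "cell"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshValidationError(
                f"face indices out of range for {len(self.vertices)} vertices"
            )
        if self.label not in VALID_LABELS:
            raise MeshValidationError(
                f"unknown mesh label {self.label!r}; expected one of {VALID_LABELS}"
            )

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def transformed(self, rotation=None, translation=None) -> "SurfaceMesh":
        """Return a rigidly transformed copy (used by property tests)."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return SurfaceMesh(v, self.faces.copy(), self.label)

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )


def _check_closed(mesh: SurfaceMesh) -> None:
    if mesh.n_faces == 0:
        raise MeshValidationError(f"mesh {mesh.label!r} is empty")
    edges = _directed_edges(mesh.faces)
    und = np.sort(edges, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if (counts == 1).any():
        raise MeshValidationError(
            f"mesh {mesh.label!r} is open: {(counts == 1).sum()} boundary edge(s)"
        )
    if (counts > 2).any():
        raise MeshValidationError(
            f"mesh {mesh.label!r} is non-manifold: "
            f"{(counts > 2).sum()} edge(s) shared by >2 faces"
        )


def _orientation_parity(mesh: SurfaceMesh) -> np.ndarray:
    """BFS over face adjacency assigning a flip parity per face.

    Two faces sharing an undirected edge agree in winding iff they traverse
    the edge in opposite directions. Returns a boolean array: True marks a
    face wound against its BFS root's orientation.
    """
    faces = mesh.faces
    m = len(faces)
    edges = _directed_edges(faces)
    face_of = np.tile(np.arange(m), 3)
    und = np.sort(edges, axis=1)
    order = np.lexsort((und[:, 1], und[:, 0]))
    und_sorted = und[order]
    same = np.all(und_sorted[:-1] == und_sorted[1:], axis=1)
    # adjacency: consecutive identical undirected edges belong to the 2 faces
    i = np.where(same)[0]
    fa, fb = face_of[order[i]], face_of[order[i + 1]]
    # windings agree iff the two directed copies are opposite
    agree = np.any(edges[order[i]] != edges[order[i + 1]], axis=1)

    neighbors: list[list[tuple[int, bool]]] = [[] for _ in range(m)]
    for a, b, ok in zip(fa, fb, agree):
        neighbors[a].append((b, ok))
        neighbors[b].append((a, ok))

    parity = np.full(m, -1, dtype=np.int8)
    for root in range(m):
        if parity[root] >= 0:
            continue
        parity[root] = 0
        stack = [root]
        while stack:
            f = stack.pop()
            for g, ok in neighbors[f]:
                want = parity[f] if ok else 1 - parity[f]
                if parity[g] < 0:
                    parity[g] = want
                    stack.append(g)
    return parity == 1


def _consistent_faces(mesh: SurfaceMesh, max_inverted_frac: float = 0.01) -> np.ndarray:
    """Return faces rewound to the majority orientation.

    Raises if more than ``max_inverted_frac`` of faces disagree with the
    majority (a mixed-orientation mesh is garbage, while a globally inverted
    one is just an exporter convention).
    """
    flipped = _orientation_parity(mesh)
    n_min = min(flipped.sum(), (~flipped).sum())
    if n_min > max_inverted_frac * len(flipped):
        raise MeshValidationError(
            f"mesh {mesh.label!r} has mixed face orientation: "
            f"{n_min}/{len(flipped)} faces wound against the majority"
        )
    faces = mesh.faces.copy()
    minority = flipped if flipped.sum() <= (~flipped).sum() else ~flipped
    faces[minority] = faces[minority][:, ::-1]
    return faces


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (µm³) of a closed, consistently oriented mesh.

    Divergence theorem: V = |Σ_faces det(v0, v1, v2)| / 6, which is exact for
    any closed triangulation and invariant under rigid-body transforms.
    """
    _check_closed(mesh)
    faces = _consistent_faces(mesh)
    v = mesh.vertices[faces]
    signed = np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0
    return float(abs(signed))


def mesh_surface_area(mesh: SurfaceMesh) -> float:
    """Total triangle area (µm²); closure is not required.

    Degenerate (zero-area) triangles contribute 0 and raise a warning with
    their count.
    """
    if mesh.n_faces == 0:
        warnings.warn(f"mesh {mesh.label!r} has no faces; area is 0", stacklevel=2)
        return 0.0
    v = mesh.vertices[mesh.faces]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    n_degen = int((areas == 0.0).sum())
    if n_degen:
        warnings.warn(
            f"mesh {mesh.label!r}: {n_degen} degenerate triangle(s) with zero area",
            stacklevel=2,
        )
    return float(areas.sum())


@dataclass
class CellGeometry:
    """The spatial domain of a single cell.

    Holds the cell-boundary mesh plus organelle meshes; the cytosolic region
    accessible to an mRNA is inside the cell and outside every mitochondrion,
    vacuole, and (optionally) the nucleus.
    """

    cell: SurfaceMesh
    mitochondria: list = field(default_factory=list)
    vacuoles: list = field(default_factory=list)
    nucleus: Optional[SurfaceMesh] = None
    cell_id: str = "cell_0"

    def organelles(self, include_nucleus: bool = True) -> list:
        orgs = list(self.mitochondria) + list(self.vacuoles)
        if include_nucleus and self.nucleus is not None:
            orgs.append(self.nucleus)
        return orgs

    def validate(self, n_containment_samples: int = 1000, rng=None) -> None:
        """Check the cell-geometry invariants.

        Volumes must be strictly positive, the summed mitochondrial volume
        must be below the cell volume, and a sample of organelle vertices
        (default 1000) must lie inside the cell mesh.
        """
        cv = mesh_volume(self.cell)
        if cv <= 0:
            raise MeshValidationError("cell volume must be strictly positive")
        mito = sum(mesh_volume(m) for m in self.mitochondria)
        if mito >= cv:
            raise MeshValidationError(
                f"mitochondrial volume {mito:.3f} µm³ is not below "
                f"cell volume {cv:.3f} µm³"
            )
        orgs = self.organelles()
        if not orgs:
            return
        verts = np.concatenate([o.vertices for o in orgs], axis=0)
        rng = np.random.default_rng(0) if rng is None else rng
        if len(verts) > n_containment_samples:
            verts = verts[
                rng.choice(len(verts), n_containment_samples, replace=False)
            ]
        inside = spatial.contains(self.cell, verts)
        if not inside.all():
            raise MeshValidationError(
                f"cell {self.cell_id}: {(~inside).sum()}/{len(verts)} sampled "
                "organelle vertices fall outside the cell mesh"
            )


@dataclass
class VolumeSummary:
    """Per-cell volumetric quantities (µm³, µm², dimensionless fractions)."""

    cell_id: str
    cell_volume: float
    mito_volume: float
    mito_surface_area: float
    vacuole_volume: float
    mito_volume_fraction: float
    effective_mito_volume_fraction: float

    def as_row(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "cell_volume_um3": self.cell_volume,
            "mito_volume_um3": self.mito_volume,
            "mito_surface_um2": self.mito_surface_area,
            "vacuole_volume_um3": self.vacuole_volume,
            "mito_volume_fraction": self.mito_volume_fraction,
            "effective_mito_volume_fraction": self.effective_mito_volume_fraction,
        }


def volume_summary(geom: CellGeometry, subtract_nucleus: bool = False) -> VolumeSummary:
    """Volumes, surface area, and (effective) mitochondrial volume fraction.

    ``mito_volume_fraction`` divides by the whole cell volume;
    ``effective_mito_volume_fraction`` divides by the accessible cytosol
    (cell minus vacuole, minus nucleus when ``subtract_nucleus`` — the two
    corrections are distinct: vacuole subtraction is used when comparing
    mutants with enlarged vacuoles, the ~7%-of-cell nucleus subtraction only
    in effective-volume modeling).
    """
    cell_v = mesh_volume(geom.cell)
    mito_v = sum(mesh_volume(m) for m in geom.mitochondria)
    mito_a = sum(mesh_surface_area(m) for m in geom.mitochondria)
    vac_v = sum(mesh_volume(m) for m in geom.vacuoles)
    nuc_v = (
        mesh_volume(geom.nucleus)
        if (subtract_nucleus and geom.nucleus is not None)
        else 0.0
    )
    if vac_v + nuc_v + mito_v >= cell_v:
        raise MeshValidationError(
            f"cell {geom.cell_id}: organelle volume "
            f"(mito {mito_v:.2f} + vacuole {vac_v:.2f} + nucleus {nuc_v:.2f}) "
            f">= cell volume {cell_v:.2f} µm³"
        )
    return VolumeSummary(
        cell_id=geom.cell_id,
        cell_volume=cell_v,
        mito_volume=mito_v,
        mito_surface_area=mito_a,
        vacuole_volume=vac_v,
        mito_volume_fraction=mito_v / cell_v,
        effective_mito_volume_fraction=mito_v / (cell_v - vac_v - nuc_v),
    )


def ellipse_depth_volume(semi_major: float, semi_minor: float) -> float:
    """Ellipsoid volume from a 2D ellipse fit, depth = shorter semi-axis.

    Image-derived (bright-field) cell and vacuole volumes come from fitting
    an ellipse to the mid-plane outline and assuming the out-of-plane
    semi-axis equals the shorter in-plane one: V = (4/3)·π·a·b².
    """
    if semi_major <= 0 or semi_minor <= 0:
        raise ValueError("ellipse semi-axes must be strictly positive")
    if semi_minor > semi_major:
        warnings.warn(
            "semi_minor > semi_major; swapping axes", stacklevel=2
        )
        semi_major, semi_minor = semi_minor, semi_major
    return float(4.0 / 3.0 * np.pi * semi_major * semi_minor**2)
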