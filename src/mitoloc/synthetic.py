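"""Synthetic cell geometries and mRNA observations.

Stands in for the microscopy inputs: per-cell triangulated geometries whose
mitochondrial volume fractions span the fermentative-to-respiratory range
(~0.05-0.35), and per-cell mRNA observations generated from the equilibrium
affinity model at a known fold-change ``A_true`` — either as count-level
binomial draws or as full trajectory tables with localization noise.

A synthetic cell is an ellipsoidal boundary (≈2.5 µm mean radius) containing
a tubular mitochondrial network of ~0.3 µm tube radius. The network skeleton
is a set of concentric helical coils with smooth random radial perturbation,
random orientation and phase: a construction that is stochastic per cell yet
guaranteed non-self-intersecting at any reachable volume fraction (a
self-avoiding random-walk skeleton jams well below the respiratory packing
density of ~50 µm of tube in a 5 µm cell). The tube is swept with a circular
cross-section whose inscribed polygon is area-corrected, and the tube radius
is adjusted against the realized mesh volume so each cell hits its target
fraction within 5%. Topology beyond "tubular" is irrelevant here: the
localization model is driven by volume fraction and surface area, not by
network branching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import trimesh

from .association import AssociationParams
from .diffusion import (
    AccessibleRegion,
    BaselineCurve,
    SimulationConfig,
    localization_proportion,
    sample_uniform_positions,
)
from .affinity import predict_localization
from .geometry import CellGeometry, SurfaceMesh, mesh_volume, volume_summary
from . import io as mio

__all__ = [
    "PopulationSpec",
    "ObservationSpec",
    "generate_cell_population",
    "generate_observations",
    "write_fixtures",
    "sweep_tube",
]


@dataclass
class PopulationSpec:
    """Synthetic cell-population parameters.

    volume_fraction_range spans fermentative to respiratory growth; cells
    are spaced evenly across it unless explicit ``volume_fractions`` are
    given. ``vacuole_fraction`` > 0 emulates enlarged-vacuole (sch9∆-like)
    cells whose accessible cytosol shrinks.
    """

    n_cells: int = 10
    volume_fraction_range: tuple = (0.05, 0.35)
    cell_radius: float = 2.5
    mito_tube_radius: float = 0.3
    vacuole_fraction: float = 0.0
    seed: int = 0
    volume_fractions: Optional[Sequence[float]] = None
    fraction_tolerance: float = 0.05  # relative tolerance on realized f
    cell_subdivisions: int = 3
    tube_sides: int = 10
    tube_arc_step: float = 0.2  # µm between skeleton samples

    def __post_init__(self):
        lo, hi = self.volume_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("volume_fraction_range must lie within (0, 1)")
        if self.cell_radius <= 0 or self.mito_tube_radius <= 0:
            raise ValueError("radii must be positive")
        if not (0 <= self.vacuole_fraction < 1):
            raise ValueError("vacuole_fraction must lie in [0, 1)")

    def targets(self) -> np.ndarray:
        if self.volume_fractions is not None:
            return np.asarray(self.volume_fractions, dtype=float)
        lo, hi = self.volume_fraction_range
        if self.n_cells == 1:
            return np.array([(lo + hi) / 2.0])
        return np.linspace(lo, hi, self.n_cells)


@dataclass
class ObservationSpec:
    """Generative parameters for synthetic mRNA observations.

    Defaults follow the study conditions: ~30 tracks per cell, 3 s frame
    interval, ~0.05 µm localization noise (spot-centroid precision at
    0.068-0.111 µm pixels), free diffusion at 0.1 µm²/s for unbound tracks.
    """

    A_true: float = 1.0
    n_tracks_per_cell: int = 30
    n_frames: int = 20
    frame_interval: float = 3.0
    noise_sd: float = 0.05
    seed: int = 0
    diffusion_coefficient: float = 0.1
    n_equilibrium_samples: int = 10000

    def __post_init__(self):
        if self.A_true < 0:
            raise ValueError("A_true must be >= 0")
        if min(self.n_tracks_per_cell, self.n_frames) < 1:
            raise ValueError("n_tracks_per_cell and n_frames must be >= 1")
        if self.frame_interval <= 0 or self.noise_sd < 0:
            raise ValueError("frame_interval must be > 0 and noise_sd >= 0")


def _cell_generator(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def sweep_tube(path: np.ndarray, radius: float, n_sides: int = 10) -> SurfaceMesh:
    """Sweep a circular cross-section along a polyline into a closed tube.

    Ring frames are parallel-transported along the path to avoid twist; the
    ring radius is inflated so the inscribed polygon matches the circle's
    area (keeping swept volume ≈ π·r²·L); flat end caps close the mesh.
    Outward orientation is enforced via the signed volume.
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        raise ValueError("path needs at least two points")
    # parallel-transport frames
    tangents = np.gradient(path, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normal = np.cross(tangents[0], [0.0, 0.0, 1.0])
    if np.linalg.norm(normal) < 1e-8:
        normal = np.cross(tangents[0], [0.0, 1.0, 0.0])
    normal /= np.linalg.norm(normal)
    r_poly = radius * np.sqrt(
        np.pi / (0.5 * n_sides * np.sin(2.0 * np.pi / n_sides))
    )
    theta = 2.0 * np.pi * np.arange(n_sides) / n_sides
    rings = np.empty((len(path), n_sides, 3))
    for i, (p, t) in enumerate(zip(path, tangents)):
        normal = normal - np.dot(normal, t) * t
        normal /= np.linalg.norm(normal)
        binormal = np.cross(t, normal)
        rings[i] = p + r_poly * (
            np.cos(theta)[:, None] * normal + np.sin(theta)[:, None] * binormal
        )

    m = len(path)
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(m - 1):
        a0 = i * n_sides
        b0 = (i + 1) * n_sides
        for j in range(n_sides):
            j1 = (j + 1) % n_sides
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    start_c = len(verts)
    end_c = len(verts) + 1
    verts = np.vstack([verts, path[0], path[-1]])
    for j in range(n_sides):
        j1 = (j + 1) % n_sides
        faces.append([start_c, j, j1])
        faces.append([end_c, (m - 1) * n_sides + j1, (m - 1) * n_sides + j])
    mesh = SurfaceMesh(verts, np.asarray(faces, dtype=np.int64), label="mitochondrion")
    # enforce outward normals
    v = mesh.vertices[mesh.faces]
    signed = np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0
    if signed < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh


def _ellipsoid_mesh(semiaxes, subdivisions: int, label: str = "cell") -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return SurfaceMesh(ico.vertices * np.asarray(semiaxes), ico.faces, label=label)


def _coil_pitch(tube_radius: float) -> float:
    eps = min(0.04, 0.15 * tube_radius)
    return 2.05 * tube_radius + 2.0 * eps + 0.03


def _min_winding_radius(tube_radius: float) -> float:
    # tightest allowed turn: keep path curvature radius above the tube radius
    return max(0.3, 1.2 * tube_radius)


def _shell_semiaxes(inner_semiaxes, tube_radius, core_radius):
    """Nested ellipsoidal shells (one per coil layer), outermost first."""
    eps = min(0.04, 0.15 * tube_radius)
    pitch = _coil_pitch(tube_radius)
    min_axis = max(
        _min_winding_radius(tube_radius) + 0.02,
        core_radius + tube_radius + 0.12,
    )
    inner = np.asarray(inner_semiaxes, dtype=float)
    # constant per-axis subtraction shrinks the normal gap by up to
    # min/max axis ratio; widen the step so adjacent shells stay >= pitch
    # apart in every direction
    step = pitch * float(max(inner)) / float(min(inner))
    shells = []
    offset = eps + 0.02
    while min(inner - offset) >= min_axis:
        shells.append(inner - offset)
        offset += step
    return shells


def _spiral_phi_speed(semiaxes, omega, phi, theta):
    """|dp/dphi| of the ellipsoidal spiral p = S·u(phi, theta(phi))."""
    a, b, c = semiaxes
    dx = a * (np.cos(phi) * np.cos(theta) - omega * np.sin(phi) * np.sin(theta))
    dy = b * (np.cos(phi) * np.sin(theta) + omega * np.sin(phi) * np.cos(theta))
    dz = -c * np.sin(phi)
    return np.sqrt(dx * dx + dy * dy + dz * dz)


def _shell_phi_range(semiaxes, tube_radius):
    m = float(min(semiaxes))
    sin_min = min(0.95, _min_winding_radius(tube_radius) / m)
    return float(np.arcsin(sin_min))


def _shell_capacity(semiaxes, pitch, tube_radius) -> float:
    """Spiral length an ellipsoidal shell can hold (numeric quadrature)."""
    m = float(min(semiaxes))
    omega = 2.0 * np.pi * m / pitch
    phi0 = _shell_phi_range(semiaxes, tube_radius)
    phi = np.linspace(phi0, np.pi - phi0, 64)
    speed = _spiral_phi_speed(semiaxes, omega, phi, omega * phi)
    return float(np.trapezoid(speed, phi))


def _coil_capacity(inner_semiaxes, tube_radius, core_radius) -> float:
    pitch = _coil_pitch(tube_radius)
    return sum(
        _shell_capacity(s, pitch, tube_radius)
        for s in _shell_semiaxes(inner_semiaxes, tube_radius, core_radius)
    )


def _spiral_shell(rng, semiaxes, pitch, eps, tube_radius, arc_step, max_length):
    """One pole-to-pole spiral winding on an ellipsoidal shell, truncated to
    ``max_length``. Adjacent turns are at least ``pitch`` apart because the
    angular turn spacing is set by the smallest semi-axis."""
    m = float(min(semiaxes))
    phi0 = _shell_phi_range(semiaxes, tube_radius)
    omega = 2.0 * np.pi * m / pitch
    phase = rng.uniform(0, 2 * np.pi)
    n_pert = int(rng.integers(2, 5))
    pert_phase = rng.uniform(0, 2 * np.pi)
    delta = eps / float(max(semiaxes))  # radial perturbation scale factor

    a, b, c = semiaxes
    phi = phi0
    pts = []
    length = 0.0
    while phi < np.pi - phi0 and length < max_length:
        theta = phase + omega * phi
        s = 1.0 + delta * np.sin(n_pert * omega * phi / (2 * np.pi) + pert_phase)
        pts.append(
            [
                s * a * np.sin(phi) * np.cos(theta),
                s * b * np.sin(phi) * np.sin(theta),
                s * c * np.cos(phi),
            ]
        )
        ds_dphi = _spiral_phi_speed(semiaxes, omega, phi, theta)
        dphi = arc_step / ds_dphi
        phi += dphi
        length += arc_step
    return np.asarray(pts), length


def _coil_skeletons(
    rng: np.random.Generator,
    length_needed: float,
    inner_semiaxes: np.ndarray,
    tube_radius: float,
    arc_step: float,
    core_radius: float = 0.0,
):
    """Concentric spherical-spiral coils totalling ``length_needed`` µm.

    The skeleton winds over nested spheres (spacing set by the tube radius
    plus the perturbation amplitude) inscribed in the cell; ``core_radius``
    reserves a central ball (e.g. for a vacuole). Raises when the requested
    length exceeds the packing capacity. Each shell gets a random
    orientation, phase and smooth radial perturbation.
    """
    eps = min(0.04, 0.15 * tube_radius)
    pitch = _coil_pitch(tube_radius)
    shells = _shell_semiaxes(inner_semiaxes, tube_radius, core_radius)
    capacity = sum(_shell_capacity(s, pitch, tube_radius) for s in shells)
    if capacity < length_needed:
        raise ValueError(
            f"target mitochondrial content unreachable: need {length_needed:.1f} µm "
            f"of tube but the cell packs at most {capacity:.1f} µm at tube radius "
            f"{tube_radius:.2f} µm"
        )

    paths = []
    remaining = length_needed
    for semiaxes_k in shells:
        if remaining < 2.0 * np.pi * _min_winding_radius(tube_radius):
            break
        pts, got = _spiral_shell(
            rng, semiaxes_k, pitch, eps, tube_radius, arc_step, remaining
        )
        if len(pts) < 4:
            continue
        paths.append(pts)
        remaining -= got
    return paths


def _make_cell(
    spec: PopulationSpec, target_f: float, index: int
) -> CellGeometry:
    rng = _cell_generator(spec.seed, index)
    jitter = rng.uniform(-0.05, 0.05, size=3)
    semiaxes = spec.cell_radius * np.array(
        [1.0 + jitter[0], 0.85 + jitter[1], 0.85 + jitter[2]]
    )
    cell = _ellipsoid_mesh(semiaxes, spec.cell_subdivisions)
    cell_vol = mesh_volume(cell)

    vacuoles = []
    core_radius = 0.0
    if spec.vacuole_fraction > 0:
        # the vacuole sits at the cell center; the coils wind around it
        r_v = (3.0 * spec.vacuole_fraction * cell_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        if r_v + spec.mito_tube_radius + 0.3 >= min(semiaxes):
            raise ValueError(
                f"vacuole fraction {spec.vacuole_fraction} does not fit inside "
                f"the cell at radius {spec.cell_radius}"
            )
        vacuoles.append(_ellipsoid_mesh((r_v, r_v, r_v), 2, label="vacuole"))
        core_radius = r_v

    # pre-escalate the tube radius until the coil packing is feasible: a
    # shorter, fatter tube needs less skeleton length (respiratory networks
    # are denser/thicker), but escalation self-limits because thicker tubes
    # also widen the coil pitch
    radius = spec.mito_tube_radius
    for _ in range(30):
        needed = target_f * cell_vol / (np.pi * radius**2)
        cap = _coil_capacity(semiaxes - (radius + 0.08), radius, core_radius)
        if cap >= 1.02 * needed:
            break
        radius *= 1.08
    else:
        raise ValueError(
            f"cell {index}: target volume fraction {target_f} is unreachable "
            f"in a cell of radius {spec.cell_radius} µm at any workable tube "
            f"radius (coil capacity {cap:.1f} µm < needed {needed:.1f} µm)"
        )

    mito = []
    realized = np.inf
    for _ in range(4):  # tube-radius refinement against realized volume
        inner = semiaxes - (radius + 0.08)
        length = target_f * cell_vol / (np.pi * radius**2)
        paths = _coil_skeletons(
            rng, length, inner, radius, spec.tube_arc_step, core_radius
        )
        mito = [sweep_tube(p, radius, n_sides=spec.tube_sides) for p in paths]
        realized = sum(mesh_volume(t) for t in mito) / cell_vol
        if abs(realized / target_f - 1.0) <= 0.6 * spec.fraction_tolerance:
            break
        radius = radius * np.sqrt(target_f / realized)
    if abs(realized / target_f - 1.0) > spec.fraction_tolerance:
        raise ValueError(
            f"cell {index}: realized volume fraction {realized:.4f} misses target "
            f"{target_f:.4f} beyond {spec.fraction_tolerance:.0%}"
        )
    return CellGeometry(
        cell=cell,
        mitochondria=mito,
        vacuoles=vacuoles,
        cell_id=f"synth_{index:03d}",
    )


def generate_cell_population(spec: PopulationSpec):
    """Generate the synthetic cell population.

    Returns ``(geometries, summaries)``; deterministic per (seed, cell
    index), and every mesh passes closure/orientation/containment
    validation.
    """
    targets = spec.targets()
    geoms = []
    for i, f in enumerate(targets):
        geom = _make_cell(spec, float(f), i)
        geom.validate()
        geoms.append(geom)
    summaries = [volume_summary(g) for g in geoms]
    return geoms, summaries


def _surface_anchor(rng, geom, offset_lo, offset_hi):
    """Random point just outside the mitochondrial surface (area-weighted)."""
    mesh = geom.mitochondria[rng.integers(len(geom.mitochondria))]
    v = mesh.vertices[mesh.faces]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    j = rng.choice(len(areas), p=areas / areas.sum())
    w = rng.dirichlet([1.0, 1.0, 1.0])
    point = w @ v[j]
    normal = cross[j] / np.linalg.norm(cross[j])
    return point + rng.uniform(offset_lo, offset_hi) * normal


def generate_observations(
    geoms,
    spec: ObservationSpec,
    baseline: BaselineCurve | float | None = None,
    params: AssociationParams | None = None,
    mode: str = "counts",
):
    """Per-cell mRNA observations from the equilibrium model at ``A_true``.

    For each cell, a baseline proportion R₀ is taken from the cell's own
    geometry by equilibrium-uniform sampling (default), or from a supplied
    baseline line/slope evaluated at its volume fraction. The expected
    localized proportion is R' = predict_localization(A_true, R₀).

    mode="counts"
        Draw n_associated ~ Binomial(n_tracks, R') per cell; returns
        ``(None, truth_table)``.
    mode="tracks"
        Additionally emit a trajectory table: associated tracks sit within
        the localization threshold of the mitochondrial surface for the
        whole track (persistence ≥ 2 frames) with Gaussian localization
        noise; the rest are confined Brownian walks re-drawn until they do
        not classify as associated, so the two generators agree
        statistically. Returns ``(trajectories, truth_table)``.
    """
    if mode not in ("counts", "tracks"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or AssociationParams()
    geoms = list(geoms)
    if not geoms:
        raise ValueError("empty cell population")

    truth_rows = []
    track_frames = []
    for i, geom in enumerate(geoms):
        rng = _cell_generator(spec.seed, 10_000 + i)
        summ = volume_summary(geom)
        f = summ.mito_volume_fraction
        if baseline is None:
            cfg = SimulationConfig(
                n_trajectories=spec.n_equilibrium_samples, seed=0
            )
            r0 = localization_proportion(geom, params, cfg, rng=rng)
        elif isinstance(baseline, BaselineCurve):
            r0 = float(np.clip(baseline.predict(f), 0.0, 1.0))
        else:
            r0 = float(np.clip(float(baseline) * f, 0.0, 1.0))
        rp = predict_localization(spec.A_true, r0)
        if mode == "counts":
            n_assoc = int(rng.binomial(spec.n_tracks_per_cell, rp))
        else:
            flags = rng.random(spec.n_tracks_per_cell) < rp
            n_assoc = int(flags.sum())
            track_frames.append(
                _emit_tracks(rng, geom, spec, params, flags)
            )
        truth_rows.append(
            {
                "cell_id": geom.cell_id,
                "f": f,
                "R0": r0,
                "Rprime_true": rp,
                "A_true": spec.A_true,
                "n_tracks": spec.n_tracks_per_cell,
                "n_associated": n_assoc,
            }
        )
    truth = pd.DataFrame(truth_rows)
    if mode == "counts":
        return None, truth
    traj = pd.concat(track_frames, ignore_index=True)
    return traj, truth


def _emit_tracks(rng, geom, spec, params, assoc_flags):
    from .association import classify_association

    region = AccessibleRegion(geom)
    from .diffusion import MeshDistanceCache

    query = MeshDistanceCache.get(geom)
    sigma = float(np.sqrt(2.0 * spec.diffusion_coefficient * spec.frame_interval))
    times = spec.frame_interval * np.arange(spec.n_frames)
    rows = []
    offset_hi = max(0.03, params.localization_threshold - 2.5 * spec.noise_sd)
    for track_id, assoc in enumerate(assoc_flags):
        for _ in range(60):
            if assoc:
                anchor = _surface_anchor(rng, geom, 0.01, offset_hi)
                pos = anchor + rng.normal(0.0, spec.noise_sd, size=(spec.n_frames, 3))
            else:
                pos = np.empty((spec.n_frames, 3))
                pos[0] = sample_uniform_positions(geom, 1, seed=rng, region=region)[0]
                for k in range(1, spec.n_frames):
                    for _try in range(200):
                        step = rng.normal(0.0, sigma, size=3)
                        cand = pos[k - 1] + step
                        if region.contains(cand[None, :])[0]:
                            pos[k] = cand
                            break
                    else:
                        pos[k] = pos[k - 1]
                pos = pos + rng.normal(0.0, spec.noise_sd, size=pos.shape)
            d = query.query(pos)
            _, got_assoc, _ = classify_association(
                times, d, params, frame_interval=spec.frame_interval
            )
            if got_assoc == assoc:
                break
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": geom.cell_id,
                    "track_id": track_id,
                    "t_s": times,
                    "x_um": pos[:, 0],
                    "y_um": pos[:, 1],
                    "z_um": pos[:, 2],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_fixtures(
    out_dir,
    geoms,
    summaries=None,
    trajectories: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    mesh_format: str = "vtk",
) -> Path:
    """Write meshes, manifest, and observation tables; returns the manifest
    path. Re-reading the fixtures through the pipeline readers reproduces
    the generation-time volume summaries."""
    geoms = list(geoms)
    if not geoms:
        raise ValueError("empty cell population: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = mio.write_manifest(geoms, out_dir, mesh_format=mesh_format)
    if summaries is None:
        summaries = [volume_summary(g) for g in geoms]
    mio.write_volume_summaries(summaries, out_dir / "volume_summaries.csv")
    if trajectories is not None:
        mio.write_trajectories(trajectories, out_dir / "trajectories.csv")
    if truth is not None:
        truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.6f")
    return manifest
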