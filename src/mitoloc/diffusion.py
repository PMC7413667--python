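"""Confined Brownian-particle simulation between cell wall and mitochondria.

The null model of mRNA localization is an ideal Brownian particle
(D = 0.1 µm²/s) with no affinity for the mitochondrial surface, confined to
the accessible cytosol: inside the cell boundary and outside mitochondria
(and vacuole/nucleus when present). Its stationary distribution is uniform
over that region, so the fraction of particles within the localization
threshold of the mitochondrial surface — the baseline localization
proportion R₀ — can be obtained either by direct equilibrium sampling
("space filling") or by time-averaging an explicit random walk; the two
agree and the walk is retained for temporal association tests.

Because a tubular mitochondrial network has surface area roughly
proportional to its volume, R₀ grows linearly with the mitochondrial volume
fraction f; the slope of that line is the baseline the affinity model
multiplies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import spatial
from .association import AssociationParams, cell_association_proportion
from .geometry import CellGeometry, volume_summary

__all__ = [
    "SimulationConfig",
    "BaselineCurve",
    "AccessibleRegion",
    "sample_uniform_positions",
    "simulate_random_walk",
    "localization_proportion",
    "brownian_baseline",
]


@dataclass
class SimulationConfig:
    """Brownian-simulation parameters.

    diffusion_coefficient : µm²/s (default 0.1)
    time_step : s; the per-axis step σ = sqrt(2·D·Δt) must resolve the
        0.19 µm localization shell and the ~0.3 µm tube radius, hence the
        0.01 s default (σ ≈ 0.045 µm)
    n_trajectories : particles per cell (≥ 40,000 for production baselines)
    n_steps : steps per trajectory
    seed : explicit; no implicit global randomness
    sampling_mode : "equilibrium_uniform" (default, direct space-filling
        sampling) or "random_walk"
    boundary_policy : "reject_resample" (redraw illegal steps; default) or
        "reflect" (specular mirror about the nearest surface)
    """

    diffusion_coefficient: float = 0.1
    time_step: float = 0.01
    n_trajectories: int = 40000
    n_steps: int = 100
    seed: Optional[int] = None
    sampling_mode: str = "equilibrium_uniform"
    boundary_policy: str = "reject_resample"
    record_interval: Optional[float] = None  # s between emitted frames

    def __post_init__(self):
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be > 0")
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.sampling_mode not in ("equilibrium_uniform", "random_walk"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")
        if self.boundary_policy not in ("reject_resample", "reflect"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")

    @property
    def step_sigma(self) -> float:
        return float(np.sqrt(2.0 * self.diffusion_coefficient * self.time_step))


def cell_rng(master_seed: int, cell_id: str) -> np.random.Generator:
    """One named generator per cell so per-cell results are reproducible
    independent of scheduling order."""
    import zlib

    key = zlib.crc32(str(cell_id).encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


class AccessibleRegion:
    """Membership test for the region between cell wall and organelles."""

    def __init__(self, geom: CellGeometry, include_nucleus: bool = True):
        self.geom = geom
        self._cell_tv = spatial.triangle_array(geom.cell.vertices, geom.cell.faces)
        orgs = geom.organelles(include_nucleus=include_nucleus)
        self._org_tv = (
            np.concatenate(
                [spatial.triangle_array(o.vertices, o.faces) for o in orgs], axis=0
            )
            if orgs
            else None
        )
        pts = self._cell_tv.reshape(-1, 3)
        self.bbox_lo = pts.min(axis=0)
        self.bbox_hi = pts.max(axis=0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        ok = spatial.contains(self._cell_tv, points)
        if self._org_tv is not None and ok.any():
            inside_org = spatial.contains(self._org_tv, points[ok])
            idx = np.flatnonzero(ok)
            ok[idx[inside_org]] = False
        return ok


def sample_uniform_positions(
    geom: CellGeometry,
    n: int,
    seed=None,
    region: AccessibleRegion | None = None,
    min_acceptance: float = 0.01,
) -> np.ndarray:
    """Uniform positions over the accessible region, by rejection sampling
    from the cell's bounding box. Reproducible given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    region = region or AccessibleRegion(geom)
    lo, hi = region.bbox_lo, region.bbox_hi
    out = np.empty((n, 3), dtype=np.float64)
    got = 0
    proposed = 0
    batch = max(2 * n, 1000)
    while got < n:
        cand = rng.uniform(lo, hi, size=(batch, 3))
        keep = cand[region.contains(cand)]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
        proposed += batch
        if proposed >= 100 * max(n, 100) and got / proposed < min_acceptance:
            raise RuntimeError(
                f"cell {geom.cell_id}: rejection-sampling acceptance "
                f"{got / proposed:.2%} < {min_acceptance:.0%}; check that the "
                "accessible region is non-empty and meshes are well-formed"
            )
    return out


def _legalize_steps(pos, prop, region, rng, sigma, policy, max_rounds=200):
    """Return legal next positions for all particles given proposals."""
    bad = ~region.contains(prop)
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_rounds:
            # vanishingly rare at sane step sizes: freeze the stragglers
            prop[bad] = pos[bad]
            break
        if policy == "reject_resample":
            prop[bad] = pos[bad] + rng.normal(0.0, sigma, size=(bad.sum(), 3))
        else:  # specular reflection about the nearest surface plane
            prop[bad] = _reflect(pos[bad], prop[bad], region)
            still = ~region.contains(prop[bad])
            if still.any():  # grazing/corner cases: fall back to resampling
                idx = np.flatnonzero(bad)[still]
                prop[idx] = pos[idx] + rng.normal(0.0, sigma, size=(len(idx), 3))
        bad = ~region.contains(prop)
    return prop


def _reflect(pos, prop, region):
    q = getattr(region, "_boundary_query", None)
    if q is None:

        class _TV:
            def __init__(self, tv):
                self.vertices = tv.reshape(-1, 3)
                self.faces = np.arange(len(tv) * 3).reshape(-1, 3)

        tvs = [region._cell_tv]
        if region._org_tv is not None:
            tvs.append(region._org_tv)
        q = spatial.MeshDistance([_TV(tv) for tv in tvs])
        region._boundary_query = q
    # mirror the illegal endpoint about the tangent plane at its nearest
    # surface point, approximated by the nearest-triangle plane
    tv = q.triangles
    _, nearest = q._tree.query(prop, k=1)
    tri = tv[np.atleast_1d(nearest)]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)
    signed = np.einsum("ij,ij->i", prop - tri[:, 0], n)
    return prop - 2.0 * signed[:, None] * n


def simulate_random_walk(
    geom: CellGeometry,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Confined Gaussian random walk; returns a trajectory table.

    Initial positions are equilibrium-uniform; each step draws an isotropic
    Gaussian displacement with per-axis variance 2·D·Δt and the boundary
    policy keeps every emitted position in the accessible region. Frames are
    recorded every ``record_interval`` seconds (default: every step).
    """
    rng = rng or np.random.default_rng(config.seed)
    region = AccessibleRegion(geom)
    sigma = config.step_sigma

    summ = volume_summary(geom)
    if summ.mito_volume > 0 and summ.mito_surface_area > 0:
        tube_radius = 2.0 * summ.mito_volume / summ.mito_surface_area
        if sigma > 0.25 * tube_radius:
            warnings.warn(
                f"step σ = {sigma:.3f} µm exceeds 25% of the estimated "
                f"mitochondrial tube radius {tube_radius:.3f} µm; reduce "
                "time_step to avoid discretization artifacts",
                stacklevel=2,
            )

    every = (
        max(1, int(round(config.record_interval / config.time_step)))
        if config.record_interval
        else 1
    )
    pos = sample_uniform_positions(geom, config.n_trajectories, seed=rng, region=region)
    frames = [(0.0, pos.copy())]
    for step in range(1, config.n_steps + 1):
        prop = pos + rng.normal(0.0, sigma, size=pos.shape)
        pos = _legalize_steps(pos, prop, region, rng, sigma, config.boundary_policy)
        if step % every == 0:
            frames.append((step * config.time_step, pos.copy()))

    n = config.n_trajectories
    rows = []
    for t, p in frames:
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": geom.cell_id,
                    "track_id": np.arange(n, dtype=np.int64),
                    "t_s": t,
                    "x_um": p[:, 0],
                    "y_um": p[:, 1],
                    "z_um": p[:, 2],
                }
            )
        )
    return (
        pd.concat(rows, ignore_index=True)
        .sort_values(["track_id", "t_s"], kind="stable")
        .reset_index(drop=True)
    )


def localization_proportion(
    geom: CellGeometry,
    params: AssociationParams | None = None,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    positions: np.ndarray | None = None,
    trajectories: pd.DataFrame | None = None,
) -> float:
    """Baseline localization proportion R₀ of a zero-affinity particle.

    equilibrium_uniform mode: fraction of uniform accessible-region samples
    within the localization threshold of the mitochondrial surface.
    random_walk mode: fraction of simulated trajectories classified
    *associated* by the association module with the same thresholds used for
    experimental data.
    """
    params = params or AssociationParams()
    config = config or SimulationConfig()
    rng = rng or np.random.default_rng(config.seed)
    if not geom.mitochondria:
        return 0.0

    if config.sampling_mode == "equilibrium_uniform" and trajectories is None:
        if positions is None:
            positions = sample_uniform_positions(
                geom, config.n_trajectories, seed=rng
            )
        if len(positions) < 1000:
            warnings.warn(
                f"only {len(positions)} samples; binomial error exceeds "
                "~1.5 percentage points",
                stacklevel=2,
            )
        d = MeshDistanceCache.get(geom).query(positions)
        return float(np.mean(d <= params.localization_threshold))

    if trajectories is None:
        trajectories = simulate_random_walk(geom, config, rng=rng)
    if trajectories["track_id"].nunique() < 1000:
        warnings.warn("fewer than 1000 trajectories; large binomial error", stacklevel=2)
    _, per_cell = cell_association_proportion(
        trajectories,
        geom,
        params,
        frame_interval=config.record_interval or config.time_step,
    )
    return float(per_cell["association_proportion"].iloc[0])


class MeshDistanceCache:
    """Memoize the mitochondrial distance query per CellGeometry object."""

    @staticmethod
    def get(geom: CellGeometry) -> spatial.MeshDistance:
        q = getattr(geom, "_mito_distance", None)
        if q is None:
            q = spatial.MeshDistance(geom.mitochondria)
            object.__setattr__(geom, "_mito_distance", q)
        return q


@dataclass
class BaselineCurve:
    """Per-cell (f, R₀) pairs and the fitted baseline line R₀ = slope·f."""

    points: pd.DataFrame  # columns cell_id, mito_volume_fraction, R0, n
    slope: float
    slope_ci: tuple
    intercept: float = 0.0
    intercept_ci: tuple = (0.0, 0.0)
    r_squared: float = float("nan")
    fit_intercept: bool = False

    def predict(self, f) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(f, dtype=float)


def brownian_baseline(
    geoms: list,
    config: SimulationConfig | None = None,
    params: AssociationParams | None = None,
    master_seed: int | None = None,
    fit_intercept: bool = False,
) -> BaselineCurve:
    """Simulate R₀ for each cell and fit the baseline line.

    By default the intercept is fixed at 0 (R₀ ∝ f; a cell without
    mitochondria localizes nothing); a free intercept is available for
    diagnostics. The 95% CI on the slope comes from the least-squares fit.
    """
    import statsmodels.api as sm

    config = config or SimulationConfig()
    params = params or AssociationParams()
    if len(geoms) < 3:
        raise ValueError("need >= 3 cells spanning a range of volume fractions")
    seed = config.seed if master_seed is None else master_seed
    rows = []
    for geom in geoms:
        rng = cell_rng(seed or 0, geom.cell_id)
        summ = volume_summary(geom)
        r0 = localization_proportion(geom, params, config, rng=rng)
        rows.append(
            {
                "cell_id": geom.cell_id,
                "mito_volume_fraction": summ.mito_volume_fraction,
                "R0": r0,
                "n": config.n_trajectories,
            }
        )
    points = pd.DataFrame(rows)
    f = points["mito_volume_fraction"].to_numpy()
    if np.ptp(f) < 1e-12:
        raise ValueError("all cells share one volume fraction; slope unidentifiable")
    y = points["R0"].to_numpy()
    X = sm.add_constant(f) if fit_intercept else f[:, None]
    res = sm.OLS(y, X).fit()
    ci = np.atleast_2d(res.conf_int(alpha=0.05))
    if fit_intercept:
        intercept, slope = res.params
        icpt_ci, slope_ci = tuple(ci[0]), tuple(ci[1])
    else:
        intercept, slope = 0.0, float(res.params[0])
        icpt_ci, slope_ci = (0.0, 0.0), tuple(ci[0])
    ss_res = float(np.sum(res.resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return BaselineCurve(
        points=points,
        slope=float(slope),
        slope_ci=tuple(float(c) for c in slope_ci),
        intercept=float(intercept),
        intercept_ci=tuple(float(c) for c in icpt_ci),
        r_squared=r2,
        fit_intercept=fit_intercept,
    )
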