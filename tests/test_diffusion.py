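"""Confined Brownian simulation: sampling, walks, baseline curve."""

import numpy as np
import pandas as pd
import pytest

from conftest import icosphere
from mitoloc.association import AssociationParams
from mitoloc.diffusion import (
    AccessibleRegion,
    SimulationConfig,
    brownian_baseline,
    localization_proportion,
    sample_uniform_positions,
    simulate_random_walk,
)
from mitoloc.geometry import CellGeometry, volume_summary


class TestUniformSampling:
    def test_symmetric_mean_in_bare_sphere(self):
        geom = CellGeometry(cell=icosphere(3, 2.0), cell_id="bare")
        pts = sample_uniform_positions(geom, 8000, seed=0)
        se = 2.0 / np.sqrt(5.0) / np.sqrt(len(pts))  # sd of a coord ~ R/sqrt(5)
        assert np.all(np.abs(pts.mean(axis=0)) < 3 * se)

    def test_never_inside_mitochondrion(self, sphere_cell):
        pts = sample_uniform_positions(sphere_cell, 5000, seed=1)
        assert np.all(np.linalg.norm(pts, axis=1) > 0.49)

    def test_shell_fraction_matches_analytic_volume_ratio(self, sphere_cell):
        # fraction within 0.19 µm of the r=0.5 sphere inside the R=2 cell
        pts = sample_uniform_positions(sphere_cell, 20000, seed=2)
        summ = volume_summary(sphere_cell)
        r = (3 * summ.mito_volume / (4 * np.pi)) ** (1 / 3)
        R = (3 * summ.cell_volume / (4 * np.pi)) ** (1 / 3)
        d = 0.19
        expected = ((r + d) ** 3 - r**3) / (R**3 - r**3)
        got = np.mean(np.linalg.norm(pts, axis=1) <= r + d)
        se = np.sqrt(expected * (1 - expected) / len(pts))
        assert abs(got - expected) < 3 * se + 2e-3

    def test_reproducible_given_seed(self, sphere_cell):
        a = sample_uniform_positions(sphere_cell, 100, seed=7)
        b = sample_uniform_positions(sphere_cell, 100, seed=7)
        assert np.array_equal(a, b)

    def test_vanishing_accessible_region_rejected(self):
        geom = CellGeometry(
            cell=icosphere(3, 1.0),
            mitochondria=[icosphere(4, 0.995, label="mitochondrion")],
            cell_id="full",
        )
        with pytest.raises(RuntimeError, match="acceptance"):
            sample_uniform_positions(geom, 500, seed=0)


class TestRandomWalk:
    def test_increment_variance_matches_2_D_dt(self):
        geom = CellGeometry(cell=icosphere(3, 5.0), cell_id="big")
        cfg = SimulationConfig(
            n_trajectories=500, n_steps=200, seed=3, time_step=0.01
        )
        traj = simulate_random_walk(geom, cfg)
        inc = (
            traj.sort_values(["track_id", "t_s"])
            .groupby("track_id")[["x_um", "y_um", "z_um"]]
            .diff()
            .dropna()
            .to_numpy()
        )
        np.testing.assert_allclose(
            inc.var(axis=0), 2 * cfg.diffusion_coefficient * cfg.time_step, rtol=0.05
        )

    def test_particle_conservation(self, sphere_cell):
        cfg = SimulationConfig(n_trajectories=200, n_steps=150, seed=4)
        traj = simulate_random_walk(sphere_cell, cfg)
        pts = traj[["x_um", "y_um", "z_um"]].to_numpy()
        r = np.linalg.norm(pts, axis=1)
        region = AccessibleRegion(sphere_cell)
        assert region.contains(pts).all()
        assert (r > 0.49).all() and (r < 2.01).all()

    def test_reflect_policy_also_conserves(self, sphere_cell):
        cfg = SimulationConfig(
            n_trajectories=100, n_steps=100, seed=5, boundary_policy="reflect"
        )
        traj = simulate_random_walk(sphere_cell, cfg)
        region = AccessibleRegion(sphere_cell)
        assert region.contains(traj[["x_um", "y_um", "z_um"]].to_numpy()).all()

    def test_coarse_step_warns_about_tube_resolution(self, small_population):
        _, geoms, _ = small_population
        cfg = SimulationConfig(
            n_trajectories=10, n_steps=2, seed=6, time_step=1.0
        )
        with pytest.warns(UserWarning, match="tube radius"):
            simulate_random_walk(geoms[0], cfg)

    def test_stationary_occupancy_matches_uniform_sampling(self, sphere_cell):
        """Chi-square: endpoint occupancy of the confined walk vs direct
        uniform rejection sampling over a spatial grid."""
        from scipy.stats import chi2

        cfg = SimulationConfig(n_trajectories=2000, n_steps=60, seed=8)
        traj = simulate_random_walk(sphere_cell, cfg)
        last = traj[traj["t_s"] == traj["t_s"].max()]
        walk_pts = last[["x_um", "y_um", "z_um"]].to_numpy()
        unif_pts = sample_uniform_positions(sphere_cell, 20000, seed=9)

        edges = np.linspace(-2.0, 2.0, 5)
        h_walk, _ = np.histogramdd(walk_pts, bins=(edges, edges, edges))
        h_unif, _ = np.histogramdd(unif_pts, bins=(edges, edges, edges))
        w, u = h_walk.ravel(), h_unif.ravel()
        keep = (w + u) >= 20
        w, u = w[keep], u[keep]
        nw, nu = w.sum(), u.sum()
        expected_w = (w + u) * nw / (nw + nu)
        expected_u = (w + u) * nu / (nw + nu)
        stat = float(np.sum((w - expected_w) ** 2 / expected_w)
                     + np.sum((u - expected_u) ** 2 / expected_u))
        dof = keep.sum() - 1
        assert stat < chi2.ppf(0.99, dof)


class TestLocalizationProportion:
    def test_no_mitochondria_gives_zero(self):
        geom = CellGeometry(cell=icosphere(3, 2.0), cell_id="bare")
        assert localization_proportion(geom, config=SimulationConfig(seed=0)) == 0.0

    def test_nested_sphere_closed_form(self, sphere_cell):
        summ = volume_summary(sphere_cell)
        r = (3 * summ.mito_volume / (4 * np.pi)) ** (1 / 3)
        R = (3 * summ.cell_volume / (4 * np.pi)) ** (1 / 3)
        d = 0.19
        expected = ((r + d) ** 3 - r**3) / (R**3 - r**3)
        cfg = SimulationConfig(n_trajectories=20000, seed=10)
        got = localization_proportion(sphere_cell, AssociationParams(), cfg)
        se = np.sqrt(expected * (1 - expected) / cfg.n_trajectories)
        assert abs(got - expected) < 2 * se + 2e-3

    def test_threshold_monotonicity(self, sphere_cell):
        cfg = SimulationConfig(n_trajectories=5000, seed=11)
        rng = np.random.default_rng(11)
        pts = sample_uniform_positions(sphere_cell, 5000, seed=rng)
        r_small = localization_proportion(
            sphere_cell, AssociationParams(localization_threshold=0.19),
            cfg, positions=pts,
        )
        r_big = localization_proportion(
            sphere_cell, AssociationParams(localization_threshold=0.38),
            cfg, positions=pts,
        )
        assert r_big >= r_small

    def test_walk_positions_reproduce_equilibrium_shell_occupancy(self, sphere_cell):
        """Time-averaged localized fraction of the confined walk equals the
        equilibrium-uniform estimate (uniform stationary distribution)."""
        params = AssociationParams()
        eq = localization_proportion(
            sphere_cell, params, SimulationConfig(n_trajectories=40000, seed=12)
        )
        cfg = SimulationConfig(n_trajectories=4000, n_steps=25, seed=13)
        traj = simulate_random_walk(sphere_cell, cfg)
        last = traj[traj["t_s"] == traj["t_s"].max()]
        from mitoloc.spatial import MeshDistance

        d = MeshDistance(sphere_cell.mitochondria).query(
            last[["x_um", "y_um", "z_um"]].to_numpy()
        )
        walk = float(np.mean(d <= params.localization_threshold))
        se = np.sqrt(eq * (1 - eq) * (1 / 40000 + 1 / 4000))
        assert abs(walk - eq) < 3 * se + 2e-3

    def test_small_sample_warns(self, sphere_cell):
        with pytest.warns(UserWarning, match="binomial error"):
            localization_proportion(
                sphere_cell,
                AssociationParams(),
                SimulationConfig(n_trajectories=200, seed=14),
            )


class TestBrownianBaseline:
    def test_exact_line_recovers_slope_with_zero_ci(self):
        import unittest.mock as mock

        geoms = [
            CellGeometry(cell=icosphere(2, 2.0), cell_id=f"c{i}") for i in range(4)
        ]
        fractions = [0.05, 0.1, 0.2, 0.3]
        with mock.patch(
            "mitoloc.diffusion.localization_proportion",
            side_effect=[2.0 * f for f in fractions],
        ), mock.patch(
            "mitoloc.diffusion.volume_summary",
            side_effect=[
                mock.Mock(mito_volume_fraction=f, mito_volume=1, mito_surface_area=10)
                for f in fractions
            ],
        ):
            curve = brownian_baseline(geoms, SimulationConfig(seed=0))
        assert curve.slope == pytest.approx(2.0, abs=1e-9)
        assert curve.slope_ci[1] - curve.slope_ci[0] == pytest.approx(0.0, abs=1e-7)

    def test_single_cell_rejected(self, sphere_cell):
        with pytest.raises(ValueError, match=">= 3 cells"):
            brownian_baseline([sphere_cell], SimulationConfig(seed=0))

    def test_identical_fractions_rejected(self, sphere_cell):
        import unittest.mock as mock

        geoms = [sphere_cell] * 3
        with mock.patch(
            "mitoloc.diffusion.localization_proportion", side_effect=[0.1] * 3
        ):
            with pytest.raises(ValueError, match="unidentifiable"):
                brownian_baseline(geoms, SimulationConfig(seed=0))

    def test_synthetic_population_linear_fit(self, small_population):
        _, geoms, _ = small_population
        cfg = SimulationConfig(n_trajectories=4000, seed=15)
        curve = brownian_baseline(geoms, cfg, AssociationParams())
        assert curve.slope > 0
        assert curve.r_squared > 0.95
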