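"""End-to-end orchestration: synth → simulate → associate → fit → predict.

A single run configuration (YAML or dict) drives the whole analysis and
produces a machine-readable report plus the per-stage CSV/JSON outputs.
Identical configuration and seed give identical data files; every number in
the report is traceable to the configuration hash and the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .affinity import (
    AffinityModel,
    calibrate_effective_volume,
    fit_affinity,
    predict_condition,
)
from .association import AssociationParams, cell_association_proportion
from .diffusion import BaselineCurve, SimulationConfig, brownian_baseline
from .geometry import volume_summary
from . import io as mio

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline",
           "compare_to_model", "rank_sum_test"]

log = logging.getLogger("mitoloc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the partial report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


@dataclass
class RunConfig:
    """Validated run configuration.

    Either a synthetic-population block (``synth``) or input paths
    (``manifest`` and optionally ``trajectories``) must be given. The
    simulation block follows the YAML convention
    ``simulation: {D_um2_s, dt_s, n_trajectories, n_steps, seed, mode,
    boundary}``.
    """

    output_dir: Path
    seed: int = 0
    synth: Optional[dict] = None
    manifest: Optional[Path] = None
    trajectories: Optional[Path] = None
    per_cell_table: Optional[Path] = None
    association: dict = dc_field(default_factory=dict)
    simulation: dict = dc_field(default_factory=dict)
    fit: dict = dc_field(default_factory=dict)
    predict_fractions: Optional[list] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path(".")
        inputs = raw.get("inputs", {}) or {}

        def _p(key):
            v = inputs.get(key)
            return (base / v) if v else None

        cfg = cls(
            output_dir=Path(raw.get("output_dir", "mitoloc_out")),
            seed=int(raw.get("seed", 0)),
            synth=raw.get("synth"),
            manifest=_p("manifest"),
            trajectories=_p("trajectories"),
            per_cell_table=_p("per_cell"),
            association=raw.get("association", {}) or {},
            simulation=raw.get("simulation", {}) or {},
            fit=raw.get("fit", {}) or {},
            predict_fractions=raw.get("predict_fractions"),
        )
        cfg.validate()
        cfg._raw = raw
        return cfg

    def validate(self) -> None:
        if self.synth is None and self.manifest is None:
            raise ValueError("config must provide a synth block or inputs.manifest")
        for path in (self.manifest, self.trajectories, self.per_cell_table):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")

    def association_params(self) -> AssociationParams:
        a = self.association
        return AssociationParams(
            localization_threshold=float(a.get("localization_threshold", 0.19)),
            min_consecutive_points=int(a.get("min_consecutive_points", 2)),
            min_duration=float(a.get("min_duration_s", 3.0)),
        )

    def simulation_config(self) -> SimulationConfig:
        s = self.simulation
        return SimulationConfig(
            diffusion_coefficient=float(s.get("D_um2_s", 0.1)),
            time_step=float(s.get("dt_s", 0.01)),
            n_trajectories=int(s.get("n_trajectories", 20000)),
            n_steps=int(s.get("n_steps", 100)),
            seed=int(s.get("seed", self.seed)),
            sampling_mode=s.get("mode", "equilibrium_uniform"),
            boundary_policy=s.get("boundary", "reject_resample"),
        )

    def config_hash(self) -> str:
        raw = getattr(self, "_raw", None) or {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "synth": self.synth,
            "association": self.association,
            "simulation": self.simulation,
            "fit": self.fit,
        }
        blob = json.dumps(raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable summary of a pipeline run."""

    config_hash: str
    seed: int
    version: str
    started: str
    stages: dict = dc_field(default_factory=dict)
    errors: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "mitoloc_version": self.version,
            "started": self.started,
            "stages": self.stages,
            "errors": self.errors,
        }

    def write(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the stages in dependency order, skipping stages whose inputs
    are absent (e.g. no trajectory data → no association/fit)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    params = config.association_params()
    sim_cfg = config.simulation_config()

    try:
        # --- geometry -----------------------------------------------------
        truth = None
        traj = None
        if config.synth is not None:
            from .synthetic import (
                ObservationSpec,
                PopulationSpec,
                generate_cell_population,
                generate_observations,
            )

            synth = dict(config.synth)
            obs_block = synth.pop("observations", None)
            pop = PopulationSpec(seed=int(synth.pop("seed", config.seed)), **synth)
            log.info("generating %d synthetic cells", pop.n_cells)
            geoms, summaries = generate_cell_population(pop)
            if obs_block is not None:
                obs_block = dict(obs_block)
                mode = obs_block.pop("mode", "tracks")
                obs = ObservationSpec(
                    seed=int(obs_block.pop("seed", config.seed)), **obs_block
                )
                traj, truth = generate_observations(
                    geoms, obs, params=params, mode=mode
                )
                if traj is not None:
                    mio.write_trajectories(traj, out / "trajectories.csv")
                truth.to_csv(out / "truth.csv", index=False, float_format="%.6f")
        else:
            log.info("loading geometry from %s", config.manifest)
            geoms = mio.load_manifest(config.manifest)
            summaries = [volume_summary(g) for g in geoms]
        mio.write_volume_summaries(summaries, out / "volume_summaries.csv")
        report.stages["geometry"] = {"n_cells": len(geoms)}

        # --- Brownian baseline -------------------------------------------
        log.info("simulating Brownian baseline (%s)", sim_cfg.sampling_mode)
        baseline = brownian_baseline(
            geoms, sim_cfg, params, master_seed=config.seed
        )
        baseline.points.to_csv(out / "baseline.csv", index=False, float_format="%.6f")
        report.stages["baseline"] = {
            "slope": baseline.slope,
            "slope_ci95": list(baseline.slope_ci),
            "r_squared": baseline.r_squared,
            "n_cells": len(baseline.points),
        }

        # --- association --------------------------------------------------
        if traj is None and config.trajectories is not None:
            traj = mio.read_trajectories(config.trajectories)
        per_cell = None
        if config.per_cell_table is not None:
            log.info("using precomputed per-cell table %s", config.per_cell_table)
            per_cell = pd.read_csv(config.per_cell_table)
        elif traj is not None:
            log.info("classifying %d trajectory points", len(traj))
            per_track, per_cell = cell_association_proportion(traj, geoms, params)
            per_track.to_csv(out / "per_track.csv", index=False)
            per_cell.to_csv(out / "per_cell.csv", index=False, float_format="%.6f")
            report.stages["association"] = {
                "n_tracks": int(len(per_track)),
                "n_cells": int(len(per_cell)),
            }
        elif truth is not None:
            # count-level synthetic observations: assemble the per-cell table
            # directly from the generated counts
            per_cell = pd.DataFrame(
                {
                    "cell_id": truth["cell_id"],
                    "mito_volume_fraction": truth["f"],
                    "n_tracks": truth["n_tracks"],
                    "n_associated": truth["n_associated"],
                    "association_proportion": truth["n_associated"]
                    / truth["n_tracks"],
                }
            )
            per_cell.to_csv(out / "per_cell.csv", index=False, float_format="%.6f")
        else:
            log.info("no observations: skipping association and fit stages")

        # --- affinity fit -------------------------------------------------
        if per_cell is not None:
            fit_block = config.fit
            eta_policy = fit_block.get("eta", 1.0)
            obs_cells = per_cell.dropna(subset=["association_proportion"])
            if eta_policy == "calibrate":
                import statsmodels.api as sm

                f = obs_cells["mito_volume_fraction"].to_numpy()
                y = obs_cells["association_proportion"].to_numpy()
                observed_slope = float(sm.OLS(y, f[:, None]).fit().params[0])
                eta = calibrate_effective_volume(observed_slope, baseline.slope)
            else:
                eta = float(eta_policy)
            fit = fit_affinity(
                obs_cells,
                baseline,
                eta=eta,
                method=fit_block.get("method", "binomial_mle"),
            )
            gene = fit_block.get("gene", "synthetic")
            fit_json = {
                "gene": gene,
                "A_hat": fit.A_hat,
                "ci95": list(fit.ci_95),
                "delta_g_kT": fit.delta_g_kT,
                "eta": eta,
                "baseline_slope": baseline.slope,
                "n_cells": fit.n_cells,
                "loglik": fit.log_likelihood,
            }
            with open(out / "fit.json", "w") as fh:
                json.dump(fit_json, fh, indent=2)
            report.stages["fit"] = fit_json

            # --- prediction curve ----------------------------------------
            fr = config.predict_fractions or list(np.round(np.arange(0.0, 0.51, 0.01), 3))
            model = AffinityModel(baseline=baseline, fit=fit, eta=eta)
            point, lo, hi = predict_condition(model, np.asarray(fr), extrapolation_limit=1.0)
            pd.DataFrame({"f": fr, "Rprime": point, "lo": lo, "hi": hi}).to_csv(
                out / "predictions.csv", index=False, float_format="%.6f"
            )
            report.stages["predict"] = {"n_points": len(fr)}
            if truth is not None:
                report.stages["truth"] = {
                    "A_true": float(truth["A_true"].iloc[0]),
                    "within_ci": bool(
                        fit.ci_95[0] <= truth["A_true"].iloc[0] <= fit.ci_95[1]
                    ),
                }
    except Exception as exc:  # partial report with an error section
        report.errors["stage_failure"] = f"{type(exc).__name__}: {exc}"
        report.write(out / "report.json")
        raise PipelineError(str(exc), report=report) from exc

    report.write(out / "report.json")
    return report


def compare_to_model(model: AffinityModel, observed_points) -> pd.DataFrame:
    """Deviation of observed condition means from the fitted model.

    ``observed_points``: records with ``condition``, ``f`` (mean volume
    fraction), ``proportion`` (mean association proportion). Returns per
    condition the model prediction at f, the residual, and whether the
    observation falls inside the 95% prediction band — the mutant-vs-model
    test.
    """
    obs = pd.DataFrame(observed_points)
    if obs.empty:
        raise ValueError("no observations to compare")
    if (obs["f"] < 0).any():
        raise ValueError("volume fractions must be >= 0")
    point, lo, hi = predict_condition(model, obs["f"].to_numpy(), extrapolation_limit=1.0)
    out = obs.copy()
    out["predicted"] = point
    out["band_lo"] = lo
    out["band_hi"] = hi
    out["residual"] = out["proportion"] - out["predicted"]
    out["inside_band"] = (out["proportion"] >= out["band_lo"]) & (
        out["proportion"] <= out["band_hi"]
    )
    return out


def rank_sum_test(x, y):
    """Two-sided Mann-Whitney U test between two per-cell proportion
    samples (the standard condition-vs-condition comparison; no
    multiple-testing correction is applied)."""
    from scipy.stats import mannwhitneyu

    res = mannwhitneyu(np.asarray(x, float), np.asarray(y, float),
                       alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
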