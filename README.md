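# mitoloc

Quantitative analysis of nuclear-encoded mRNA localization to the
mitochondrial surface in budding yeast, built around live-cell
single-molecule mRNA tracking (MS2-MCP-style) and MitoGraph-style 3D
mitochondrial reconstructions.

As yeast shift from fermentative to respiratory growth the mitochondrial
network expands, raising the **mitochondrial volume fraction**
f = V_mito / V_cell. For an mRNA diffusing in the cytosol this alone raises
the chance of being near the mitochondrial surface. `mitoloc` implements the
full quantitative chain needed to separate that geometric effect from
sequence-specific binding:

1. **geometry** — closed triangulated surfaces (legacy-ASCII VTK or PLY) for
   cell, mitochondria, vacuole, nucleus; divergence-theorem volumes, surface
   areas, raw and accessible-cytosol ("effective") volume fractions, and a
   2D-ellipse volume estimator for bright-field data.
2. **association** — exact point-to-triangulated-surface distances
   (k-d-pruned, oracle-equal to brute force); an mRNA is *localized* within
   0.19 µm of the surface (twice the mode of a surface-bound reference's
   distance histogram) and *associated* when localized for ≥ 2 consecutive
   time points spanning ≥ 3 s; per-cell association proportions.
3. **diffusion** — ideal Brownian particles (D = 0.1 µm²/s) confined between
   cell wall and organelle surfaces, by direct equilibrium-uniform sampling
   or an explicit confined random walk; yields the zero-affinity baseline
   R₀(f) ≈ slope·f.
4. **affinity** — the equilibrium binding model K = A·K₀. The localization
   proportion of an mRNA with affinity fold-change A is

       R′ = A·R₀ / (1 + (A − 1)·R₀)

   with A = 1 the freely diffusing baseline and ΔΔG = −k_B·T·ln A. A is
   fitted per gene by binomial maximum likelihood over cells with a
   profile-likelihood 95% CI, optionally after an effective-cell-volume
   rescaling η (the observed-vs-ideal slope ratio; ~0.66 in calibrated
   data). Also includes the translation-competency duration
   (ORF length − MTS exposure) / 9.5 aa s⁻¹.
5. **synthetic** — generator for realistic cell geometries (ellipsoidal
   cells, coiled tubular mitochondrial networks hitting target volume
   fractions within 5%, optional vacuoles) and for count- or
   trajectory-level mRNA observations drawn from the equilibrium model at a
   known A.
6. **pipeline** — one-configuration end-to-end runs with a deterministic,
   seed-traceable report, plus a `mitoloc` CLI
   (`synth` / `simulate` / `associate` / `fit` / `predict` / `pipeline`).

## Worked example

Fit the affinity of a synthetic mRNA generated at A = 2.4 from a single
YAML configuration:

```yaml
# cfg.yaml
seed: 3
output_dir: mitorun
synth:
  n_cells: 4
  volume_fraction_range: [0.08, 0.3]
  observations: {A_true: 2.4, n_tracks_per_cell: 25, mode: counts,
                 n_equilibrium_samples: 3000}
simulation: {n_trajectories: 3000}
fit: {gene: SYN, eta: 1.0}
```

```sh
$ mitoloc pipeline --config cfg.yaml
{
  "gene": "SYN",
  "A_hat": 2.30644404316669,
  "ci95": [1.5206036843826753, 3.5067145336761456],
  "delta_g_kT": -0.8357069632257572,
  "eta": 1.0,
  "baseline_slope": 1.7951823443786,
  "n_cells": 4,
  "loglik": -65.80662954412621
}
```

Reading the output: the simulated Brownian baseline over these four cells
has slope ≈ 1.80 (R₀ per unit volume fraction); the binomial-MLE affinity
estimate is A ≈ 2.31 with a 95% CI of [1.52, 3.51] that covers the
generating value 2.4; the corresponding free-energy gain of localization is
≈ −0.84 k_B·T. The output directory holds the per-cell volume summaries,
baseline curve, per-cell association table, fit JSON, prediction curve
(`f,Rprime,lo,hi`), and a provenance report (config hash, seed, version).

Library use mirrors the CLI, e.g.:

```python
from mitoloc import (PopulationSpec, generate_cell_population,
                     SimulationConfig, brownian_baseline, fit_affinity)

geoms, summaries = generate_cell_population(PopulationSpec(n_cells=10, seed=1))
curve = brownian_baseline(geoms, SimulationConfig(n_trajectories=20000, seed=1))
```

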