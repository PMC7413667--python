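# Methods

## The model

An mRNA in the cytosol of a yeast cell is treated as a particle that can be
free or bound to the mitochondrial outer surface, in mass-action
equilibrium with the available surface:

    mRNA_free + mito_surface ⇌ mRNA_localized,   K = [mRNA_loc] / ([mRNA_free][surface])

A particle with no specific affinity (an ideal Brownian particle) still
spends a fraction R₀ of its time within the localization threshold of the
surface simply because the surface occupies part of the cell. That fraction
defines the baseline equilibrium constant K₀ through
R₀ = K₀[surface] / (1 + K₀[surface]). A sequence-specific mRNA carries
K = A·K₀ with a dimensionless affinity fold-change A (equivalently a
relative binding free energy ΔΔG = −k_B·T·ln A). Substituting
K₀[surface] = R₀/(1−R₀) gives the closed form used throughout:

    R′(A, R₀) = A·R₀ / (1 + (A−1)·R₀)

which is the identity at A = 1, saturates at 1 as A → ∞, is strictly
increasing in both arguments on the interior, and has the exact algebraic
inverse R₀ = R′ / (A − (A−1)R′). The library verifies the mass-action
composition identity, the inverse round trip (to 1e-12), and both
monotonicity properties as tests.

Because a tubular mitochondrial network of roughly constant tube radius has
surface area proportional to its volume, R₀ grows essentially linearly with
the mitochondrial volume fraction f: R₀ ≈ slope·f. The pipeline therefore
reduces a cell's geometry to f, maps it to R₀ through a simulated baseline
line, and explains per-gene localization data with the single parameter A.

## Geometry

Meshes are closed, consistently oriented triangle surfaces in µm. Volumes
use the signed divergence-theorem sum with the absolute value taken at the
end, so globally inverted meshes (an exporter convention) are accepted;
meshes with open edges, non-manifold edges, or more than 1% of faces wound
against the majority (determined by BFS parity over the face-adjacency
graph) are rejected with an error naming the defect. Two volume-fraction
denominators are provided: the whole cell volume (the default x-axis of all
baseline fits) and the accessible cytosol, cell minus vacuole — used when
comparing mutants with enlarged vacuoles — with the ~7%-of-volume nucleus
subtracted only on request, since the two corrections arise in different
analyses. For bright-field data without meshes, cell and vacuole volumes
can be estimated from a fitted mid-plane ellipse as (4/3)πab², taking the
depth semi-axis equal to the shorter in-plane one.

## Distances and association calls

Distances from mRNA positions to the mitochondrial surface are exact
point-to-triangle distances, minimized over all triangles of all
mitochondrial components. A k-d tree over triangle centroids prunes
candidates with a provably lossless bound (a triangle can only beat the
current best distance u if its centroid lies within u + 2·r_max of the
query, r_max bounding the triangle circumradii), so the accelerated query
equals exhaustive search bit-for-bit; the brute-force path is kept and
asserted equal in tests. Containment (for confinement and sampling) uses
fixed-direction ray-crossing parity with grazing rays detected and re-tested
by the generalized winding number; the two methods are asserted equal on
every geometry class used in tests.

An mRNA is **localized** at a time point when its distance is ≤ 0.19 µm.
The threshold is defined as twice the mode of the distance histogram of a
constitutively surface-bound reference population under
elongation+transcription arrest; `derive_localization_threshold` implements
exactly that doubling with a default 0.01 µm histogram bin (below the
imaging pixel size, far above float noise), and the pipeline default is the
calibrated 0.19 µm. An mRNA is **associated** when some run of consecutive
localized time points has ≥ 2 members and spans ≥ 3 s at the ~3 s frame
interval. Gaps in a track break runs — no interpolation — which is the
conservative reading of "consecutive". Cells with zero tracks report a
missing proportion, never 0, so population means are unbiased.

## Brownian baseline

The zero-affinity reference is an ideal Brownian particle, D = 0.1 µm²/s,
confined to the accessible region (inside the cell, outside mitochondria,
vacuole, and nucleus). Its stationary distribution is uniform over that
region, so the default baseline estimator simply draws equilibrium-uniform
positions by rejection sampling from the cell bounding box and measures the
fraction within the threshold of the surface. An explicit random walk
(default Δt = 0.01 s, per-axis step σ = √(2DΔt) ≈ 0.045 µm, small relative
to the ~0.3 µm tube radius and the 0.19 µm shell) is retained for temporal
association tests; illegal steps are redrawn ("reject-resample", the
default, which preserves detailed balance well at small steps) or
specularly reflected about the nearest surface plane. Tests verify particle
conservation, the per-step variance, and that the walk's occupancy matches
equilibrium sampling (chi-square over a spatial grid, and shell-occupancy
agreement within binomial error).

Note one estimand subtlety: the *association* proportion of a random-walk
trajectory (persistence over ≥ 2 frames, 3 s apart) is not the same
quantity as the instantaneous localized fraction — at 3 s frames the
positions are nearly decorrelated, so 2-frame persistence behaves like p²
rather than p. Walk-vs-equilibrium agreement is therefore checked on
instantaneous shell occupancy (equal by ergodicity), while the
association-based random-walk mode remains available for like-for-like
comparison with experimental tracks.

Per-cell (f, R₀) pairs are fitted by least squares with the intercept fixed
at 0 (a cell without mitochondria localizes nothing); a free-intercept fit
is available for diagnostics, and the 95% CI on the slope comes from the
regression.

### Linearity and its limits

R₀ is the localized fraction of particles that live in the *accessible*
volume, so to first order R₀ ≈ c·f/(1−f): linear in f with a mild upward
convexity as the network occupies more of the cell. Over the full
fermentative-to-respiratory range (f from 0.05 to 0.35) the free-intercept
line fits with R² ≈ 0.997 but acquires a small negative intercept
(≈ −0.03 at the default 0.19 µm threshold and 0.3 µm tube radius, where the
localization shell is a substantial fraction of the tube cross-section).
This is a property of the model geometry, not noise; analyses that assume
strict proportionality should restrict to narrower f ranges or use the
through-origin slope.

## Affinity fitting

Per-gene data are per-cell triples (f, n_tracks, n_associated). The
likelihood is binomial per cell, n_associated ~ Binomial(n_tracks,
R′(A, slope·f/η)), maximized over log A on [ln 1e-3, ln 1e3] by bounded 1-D
search; predictions are clamped to [1e-9, 1−1e-9]. Binomial MLE was chosen
because per-cell track counts vary and should be weighted accordingly; an
unweighted least-squares objective on proportions is provided for
sensitivity analysis. The 95% CI is the profile-likelihood interval (χ²,
1 df); estimates at the search boundary, or from all-associated /
none-associated data, are flagged and yield one-sided intervals. Parameter
recovery is verified at A ∈ {1, 2.4, 8.8}: the median estimate over
replicates of 30 cells × 30 tracks is within 10% of truth and CI coverage
is ≥ 90%.

The effective-volume factor η = (ideal Brownian slope)/(observed slope)
absorbs cytosol-excluding organelles absent from the simulated geometry
(nucleus ~7%, vacuole ~10%, ER, lipid droplets); measured fractions are
rescaled f → f/η before model evaluation, one global η per dataset. η is
applied consistently in both calibration and fitting; values above 1.2
(observed baseline shallower than ideal) trigger a warning because they
contradict the exclusion rationale.

Condition predictions (mutants, drug treatments) evaluate R′(A_hat,
slope·f/η) with a band from the CI endpoints of A (valid by monotonicity of
R′ in A), and `compare_to_model` reports residuals and band membership of
observed condition means. Condition-vs-condition comparisons of per-cell
proportions use the two-sided Mann-Whitney U test with no multiple-testing
correction, matching common practice for these small per-cell samples.

The translation-competency duration — how long a nascent-chain-attached
mRNA exposes its targeting sequence and can be captured — is
(ORF length − exposure codon)/rate with the canonical elongation rate
9.5 aa/s; a 300-aa reporter gives ≈ 31.6 s.

## Synthetic data

The generator stands in for microscopy-derived inputs. Each synthetic cell
is an ellipsoidal boundary (mean radius 2.5 µm, mild random axis jitter)
containing a tubular mitochondrial network of tube radius 0.3 µm built by
sweeping an area-corrected circular cross-section along a skeleton of
nested ellipsoidal "ball of yarn" spiral coils. The coil construction was
chosen over a self-avoiding random-walk skeleton deliberately: at
respiratory fractions the network needs ~50 µm of tube inside a ~5 µm cell,
a packing density at which random-walk self-avoidance stalls, while
concentric spirals with guaranteed inter-turn and inter-shell clearance
(set by the tube diameter plus the perturbation amplitude) reach those
fractions deterministically. Per-cell randomness enters through axis
jitter, spiral phases, and smooth radial perturbations; everything is
deterministic given (seed, cell index). The tube radius is refined against
the realized mesh volume so each cell hits its target fraction within 5%
(and is allowed to thicken when a target is otherwise unreachable —
respiratory networks are denser and thicker); genuinely impossible targets
raise an error with the packing diagnosis. Optional vacuoles are central
spheres the coils wind around. All meshes are watertight and consistently
oriented by construction and are re-validated (closure, orientation,
sampled containment) on generation.

Observations are generated from the equilibrium model at a known A_true.
Per cell, R₀ comes from the cell's *own* geometry by equilibrium-uniform
sampling (so geometric heterogeneity propagates), or from a supplied
baseline slope. The count-level generator draws n_associated ~
Binomial(n_tracks, R′(A_true, R₀)). The trajectory-level generator emits
tracks at the 3 s frame interval with 0.05 µm Gaussian localization noise
(≈ spot-centroid precision at 0.068–0.111 µm pixels): associated tracks
are anchored within the threshold of the surface for the whole track;
unassociated tracks are confined Brownian walks redrawn until the
classifier does not call them associated, so the two generators produce
statistically indistinguishable per-cell counts (verified by a pooled
chi-square test). What the synthetic data deliberately omits: detection
failures and tracking errors, intensity-dependent detectability, nuclear
retention, network branching/fission-fusion dynamics, and camera/PSF
effects — so passing tests demonstrate correctness of the quantitative
chain, not robustness to those real-data artifacts.

## Numerical choices and problem sizes

Defaults: localization threshold 0.19 µm; frame interval 3 s; D = 0.1
µm²/s; walk Δt = 0.01 s; A searched in [1e-3, 1e3]; histogram bin 0.01 µm;
distance queries exact (no tolerance); mode ties resolved to the lowest
bin with a warning; containment by ray parity with winding-number
fallback on grazing rays. The test suite and the acceptance script size
their simulations for desk-scale runs — 10–30 cells per population,
10,000–40,000 equilibrium samples per cell, 50 fit replicates — sizes at
which the binomial/regression tolerances asserted in the tests are several
times the corresponding standard errors.

## Known limitations

- The baseline line is calibrated on simulated geometry; applying it to
  real cells requires the η rescaling, and η lumps all unmodeled excluded
  volume into one scalar.
- The equilibrium model has no kinetics: binding on/off rates,
  translation-coupled capture dynamics, and motor transport are outside its
  scope; A is an effective, gene-level constant.
- The mild f/(1−f) convexity of R₀ (see above) means "slope" is a
  range-dependent summary at high volume fractions.
- Specular reflection at a faceted boundary is approximate near edges; the
  default reject-resample policy is the verified one.
- Mode-based threshold calibration needs a genuinely surface-saturated
  reference population; on diffuse references the doubled mode is
  meaningless.
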