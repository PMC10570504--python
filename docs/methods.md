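# Methods

## Overview

`vesselrom` is a proof-of-concept reduced-order model (ROM) for steady
haemodynamics in single, unbranched, coronary-artery-like vessels. The
pipeline couples four components: a synthetic geometry generator, a quasi-1D
non-Newtonian flow surrogate, a mesh-domain common-base proper orthogonal
decomposition (cPOD) of the field ensembles, and a shape-to-coefficient
regression (2-D t-SNE embedding + chained random forests). The working
assumption throughout is that vessel *shape* is the dominant factor in the
steady pressure and wall-shear-stress (WSS) fields, that shape varies
smoothly across the ensemble, and that the fields therefore live close to a
low-dimensional linear subspace spanned by a handful of POD modes.

## Synthetic geometry generator

The generator emulates the statistical structure of a phantom dataset built
from a handful of real artery reconstructions: a few geometrically distinct
parents, each surrounded by a cloud of small smooth perturbations.

* **Reference vessels.** Seven straight tubes, length L = 30 mm, baseline
  radius 1.5 mm (typical proximal coronary calibre), each modulated by a
  fixed low-frequency cosine with a parent-specific amplitude (0–0.18),
  frequency (0–2 cycles/length) and phase. The parents are synthetic
  stand-ins: no patient data is used or required.
* **Perturbations.** Each phantom multiplies its parent's radius profile by
  `1 + Σ_j [a_j sin(2π f_j s/L + φ_j) + d_j]`, j = 1, 2, with parameters
  drawn uniformly within |a_j| ≤ 0.08, |d_j| ≤ 0.03, f_j ∈ [0.5, 2.5]
  cycles/length, φ_j ∈ [0, 2π). The bounds keep the worst-case radius
  deviation at 22 % — "small but significant": large enough to change the
  flow appreciably (WSS scales as r⁻³), small enough that the solution
  ensemble stays low-rank and every phantom remains a plausible vessel
  (bracket ≥ 0.78 > 0, enforced structurally and re-checked per draw).
* **Meshing.** A structured tube grid: `n_axial` uniform stations (default
  101), `n_circ` wall points per station (default 32), `n_radial` interior
  rings plus an axis node per station (default 4), giving Ns = 3232 surface
  and Nv = 13 029 volume nodes. Node ordering is frozen (station-major; wall
  ring by angle; volume: axis node, then rings inner→outer, each by angle),
  so all meshes at one resolution share a common node basis — the property
  cPOD depends on. Interior ring radii sit at fractions l/(n_radial+1) of
  the local wall radius so no volume node duplicates a wall node. The
  volume/surface imbalance (≈ 4:1) mirrors the imbalance a hex/prism CFD
  mesh would have.
* **What it does not emulate.** Curvature, torsion, branching, lumen
  eccentricity, imaging noise, and inter-patient radius variability beyond
  the parent modulations. Passing tests therefore demonstrate the pipeline's
  mechanics and its compression/regression behaviour on smooth tube-like
  ensembles, not clinical accuracy on real arteries.

Reproducibility: one `numpy.random.SeedSequence` per parent, spawned from
the dataset seed, makes every draw bitwise reproducible.

## Surrogate flow solver

A deliberate stand-in for a 3-D CFD solve, chosen so the geometry→field map
is smooth, deterministic and desk-scale while preserving the physics the ROM
exploits (r⁻³/r⁻⁴ sensitivity of WSS and pressure drop to radius):

* Mass conservation fixes Q = U_in π r(0)² with U_in = 100 cm/s.
* Wall shear rate per station: Poiseuille estimate γ̇_w = 4Q/(πr³). No
  fixed-point iteration on the non-Newtonian velocity-profile shape is
  attempted; the estimate is exact for a parabolic profile and documented so
  it can be refined.
* Carreau–Yasuda kinematic viscosity ν(γ̇) with ν∞ = 3.45×10⁻⁶ m²/s,
  ν₀ = 56×10⁻⁶ m²/s, τ = 3.313 s, α = 2, n = 0.3568 (a standard blood fit).
  WSS: τ_w = ρ ν(γ̇_w) γ̇_w with ρ = 1060 kg/m³ (blood density; needed to
  express stresses in Pa since the rheology is kinematic).
* Pressure: axial force balance dp/ds = −2τ_w/r integrated upstream from the
  zero-pressure outlet by the trapezoidal rule; radial pressure variation is
  neglected (plug assignment per station), consistent with quasi-1D.

In the Newtonian limit (ν₀ → ν∞) on a uniform tube this reduces exactly to
the Poiseuille pressure drop Δp = 8ρνLQ/(πr⁴), which the tests verify to
better than 0.1 %. Invariants: zero outlet pressure, strictly positive WSS,
pressure non-increasing downstream, every evaluated viscosity in (ν∞, ν₀].
Turbulence closures and wall functions are intentionally out of scope; the
solver registry (`register_solver`) lets a full CFD backend replace the
surrogate without touching the rest of the pipeline.

## Common-base POD

The M field vectors are stacked into A (M × N) and factored A = U D Vᵀ.
Choices that matter:

* **No mean-centering by default.** The stacked matrix is factored directly,
  so mode 1 carries the ensemble-mean field pattern; centering is available
  as an option (`center=True`).
* **Energy = singular-value sum.** The truncation criterion uses
  Σ_{i≤k} σ_i / Σ σ_i. The conventional σ² (variance) fraction is computed
  alongside and written to the singular-value CSV; the sum criterion is the
  stricter of the two, so a k chosen by it also satisfies the σ² criterion.
* **Snapshot path.** With N ≫ M the decomposition goes through the M × M
  matrix A Aᵀ (eigendecomposition), followed by a small SVD of the projected
  matrix UᵀA. The polish step costs one extra thin SVD but restores mode
  orthonormality to machine precision — the raw snapshot eigenvector route
  loses orthogonality on trailing near-noise modes because it effectively
  squares the condition number. Snapshot and direct paths agree to 1e-8 and
  this equivalence is asserted in tests.
* **Determinism.** Sign indeterminacy of SVD factors is fixed by forcing the
  largest-magnitude entry of each mode non-negative.
* Ranks with σ below `max(M,N)·eps·σ₁` are treated as numerical zeros and
  dropped.
* Pressure and WSS are decomposed independently into two bases; the default
  retention is k = 10 modes (an energy-threshold alternative is available).

## Shape embedding

Each mesh is represented by its centroid-centred, flattened node coordinates
(length 3(Ns+Nv)). Meshes are *not* scale-normalised: the radius scale is
physically informative. t-SNE (scikit-learn, PCA initialisation, fixed seed,
default perplexity 30) maps the training set to 2-D; perplexity is exposed
as configuration, not auto-tuned.

t-SNE has no native out-of-sample map, so unseen meshes are placed by k-NN
Gaussian-kernel interpolation in the *input* space: w_j ∝
exp(−‖x−x_j‖²/2h²) over the k = 5 nearest training meshes, with h the median
of those k distances unless fixed. A query identical to a training mesh
returns that mesh's coordinate exactly (checked by row equality, not by a
floating-point distance threshold). The rule is deterministic, continuous
away from neighbour-set changes, and degrades gracefully (nearest-neighbour
fallback if all kernel weights underflow).

## Coefficient regression

One `RandomForestRegressor` (70 trees, max depth 20 — the tuned values for
this task) per retained mode, organised as a regressor chain in descending-σ
order: the model for mode j sees [tsne_x, tsne_y, ĉ₁, …, ĉ_{j−1}]. During
*training* the upstream features are the already-fitted forests' in-sample
predictions, matching what the chain sees at predict time; the variant that
trains on true upstream coefficients is available (`cascade="true"`). Each
forest gets a distinct derived seed. Coefficient accuracy is summarised as
RMSE divided by the training-set range of that coefficient (×100); the
normalisation is a package choice, stated here because several alternatives
(std, mean magnitude) exist. The train/test split is 80/20, shuffled with a
derived seed, and metrics are averaged over 10 seeded split repeats
(`n_split_repeats`); chain-order sensitivity (default vs reversed) can be
logged via `chain_order_check`.

## Error metrics

NMAE and NRMSE compare reconstructed and ground-truth fields node-wise and
normalise by the field's range max(f) − min(f) over the *full* dataset
(train + test), in percent. NMAE ≤ NRMSE holds per mesh (power-mean
inequality) and is asserted everywhere. Ensemble results are reported as
mean ± standard deviation over test meshes.

## Pipeline and reproducibility

A master seed deterministically derives one sub-seed per stage
(`SeedSequence(seed).spawn`, one child per stage in fixed order, first state
word folded below 2³¹), so stages can be rerun in isolation and a rerun with
the same seed reproduces every exported table bit for bit. Expensive stage
outputs (solved field matrices, the fitted embedding) are cached in the run
directory keyed by a hash of the configuration. The end-to-end contract that
the ML reconstruction error cannot fall below the pure 10-mode truncation
error on the same meshes is checked on each run's reports.

## Problem sizes

The default configuration (1407 meshes, 101 × 32 × 4 grid) is the package's
full-scale study and is what `scripts/acceptance.py` runs; it completes in
well under a minute on one CPU because the surrogate solve is vectorised per
station and the POD uses the snapshot path. Unit and property tests run at
reduced scale (21-station grids, 27–77 meshes) chosen to exercise every code
path while keeping the suite fast.

## Known limitations

* Steady flow only: no pulsatility, no quasi-steady rescaling across the
  cardiac cycle.
* Rigid walls (no fluid–structure interaction), straight centerlines, no
  side branches or bifurcations.
* The quasi-1D surrogate has no secondary flows, flow separation or
  turbulence; on strongly constricted geometries its fields are qualitative.
* t-SNE is used strictly at 2-D; higher-dimensional embeddings and
  uncertainty-quantifying regressors (e.g. Gaussian processes) are out of
  scope.
* Error statistics on the synthetic ensemble say nothing quantitative about
  real arteries; they validate the machinery, not clinical accuracy.
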