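# Methods

This note documents the models, conventions and numerical choices behind
`morphoevo`, and what the synthetic-data tests do and do not demonstrate.

## Shape variables

**Superimposition.** Each configuration is centred and scaled to unit
centroid size, then rotated iteratively to the evolving consensus until
the consensus changes by less than 1e-10 (full Procrustes fit; no variable
scaling). GPA output is unique only up to a global rotation, so the
consensus orientation is fixed deterministically: its major principal axis
is aligned with +x and the rotation (of the two satisfying that) with
landmark 1 below the x-axis is chosen. This makes alignment invariant —
to about 1e-8 — under similarity transforms and re-ordering of the
inputs, which the test suite exploits. All-collinear configurations are
rejected as degenerate.

**Semi-landmark sliding.** Semi-landmarks slide along the chord between
their curve neighbours to minimise the thin-plate-spline bending energy
relative to a reference. The bending-energy matrix is the upper-left
block of the inverse TPS system matrix with kernel `U(r) = r² log r²`;
it annihilates affine displacements, so affine deformation is free. Per
specimen the slide amounts solve the energy quadratic exactly (a small
linear system), which guarantees the descent property checked by the
tests. Sliding alternates with re-superimposition; the reference is the
current sample mean, updated each outer iteration (5 iterations by
default, stopping when the summed energy changes by < 1e-6). Whether the
reference should be the sample mean or an external template is an open
convention; the sample mean is the default and an explicit `reference`
argument overrides it.

**Tangent projection.** Aligned shapes are projected orthogonally onto
the affine plane through the mean shape orthogonal to it (not
stereographically); at the disparity levels studied here (tangent
distances < 0.3) the two conventions differ negligibly, and the tests
verify 1% agreement between tangent and full Procrustes distances below
0.05. Disparity P² is the mean squared tangent distance to the sample
mean.

## Phylogenetic machinery

Trees are parsed/written via dendropy; polytomies are resolved randomly
(seeded) with zero-length inserted edges, preserving patristic distances.
Inside PIC and ancestral-state computations only, zero branch lengths are
floored at 1e-8 x tree depth to keep divisions finite.

Contrasts use Felsenstein's pruning algorithm with the usual
branch-length inflation. Ancestral states are the branch-length-weighted
squared-change-parsimony states — identical to the ML/GLS estimates under
BM — computed as the Gaussian conditional means given the tips at the GLS
root; an unweighted mode (all branches equal) reproduces the classic
equal-weight convention. Tests verify both against an independent
graph-Laplacian minimiser and against ape (`pic`, `ace`) through Rscript.

## Allometry

Shape contrasts are regressed through the origin on log-centroid-size
contrasts; the effect size is the % of total contrast variance explained.
Significance uses permutations of the size contrasts against the shape
rows with the +1 correction, `p = (1 + #{perm >= obs}) / (n_perm + 1)`
(10,000 permutations by default). Species-level size correction reuses
the contrast-estimated slopes (two-step phylogenetic correction), applied
by default only when p < 0.05 (`size_correction_policy` can force
always/never). Because it is ambiguous whether reported percentages in
comparative studies are contrast-based or species-level, the pipeline
reports both (`pct_var_size`, `pct_var_size_species`).

## Evolutionary models

All models are covariance transforms of the BM matrix **C** with total
depth T (see README for formulas). Conventions chosen for comparability:

* the δ transform is rescaled by `T^{1-δ}` to preserve total depth, so
  σ² keeps its per-unit-depth meaning across models;
* the OU covariance is scaled so that α → 0 recovers **C** exactly;
* the combined model applies the δ depth-power transform first, then the
  OU transform on the δ-rescaled (still ultrametric) tree — "rate shift in
  time, then attraction". The opposite composition order would be an
  equally defensible convention; this one is fixed and documented. The
  (δ, α) pair is optimised jointly (Nelder–Mead from the best point of a
  fixed grid, in a bounded sigmoid re-parameterisation); a `plugin` mode
  instead evaluates the combined model at the separately fitted δ̂ and α̂.

The likelihood is the pooled-rate multivariate form: p traits independent
with one shared σ², root states and σ² profiled analytically, so each
model adds only its transform parameter(s). Parameter counts: BM 2,
OU/EB/δ 3, δ+OU 4 (the root-state block counted once). Model choice is by
AIC (not AICc), ties broken toward fewer parameters. Optimisation is
deterministic: bounded Brent for 1-D (α ∈ [1e-8, 50/T], δ ∈ [0.01, 3],
ρ ∈ [-10/T, 10/T]), no randomness anywhere in fitting.

σ²mult is the BM-profiled pooled rate — the average per-dimension rate of
the trait block. **Dimension reduction:** Procrustes tangent coordinates
are rank-deficient (four similarity dimensions carry no variance), so a
per-dimension rate computed on raw 2k coordinates would be deflated by a
region-dependent factor 2k/rank, corrupting between-region rate ratios.
The pipeline therefore reduces the (size-corrected) tangent data to the
leading principal components reaching 95% cumulative variance before
model fitting and rate estimation (on by default, logged; configurable
via `pca_reduce`/`pca_variance`). Disparity P², ancestral reconstruction
and the P-matrix use the full tangent coordinates.

## Lability

The default P-matrix is the covariance of the reconstructed shapes across
all internal nodes, with the root reconstruction as the trait-mean vector;
a contrasts-based evolutionary rate matrix is available as the alternative
source, since the literature phrase "P-matrix of the ancestral
reconstruction" does not pin down one sample. Mean standardization
divides each element by the outer product of trait means; tangent
coordinates can be arbitrarily close to zero, so means below
1e-3 x ||means|| are floored at that signed bound (an unstandardized mode
is provided). Selection gradients are normalised Gaussian draws (uniform
on the sphere); flexibility is the cosine of the raw response and
gradient vectors, not a centred correlation.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the package's study conditions: pure-birth
trees rescaled to unit depth; six independent traits per region with
per-depth rates of order 0.005–0.010, giving disparities (P² ~ 0.02–0.08)
in the range a broad mammalian skull sample shows; an injected allometric
component of 2.3% of shape variance (matching the size effect typical of
such data); log sizes evolving as BM with stationary spread 0.3;
digitisation noise of 0.002 coordinate units on a unit-size template; and
similarity-transform nuisance (random rotation, translation, scale,
pixel-scale factors written to TPS `SCALE=` records).

Trait deviations are mapped through an orthonormal basis of the template's
tangent space — per region, through the region sub-template's own basis
scaled by the region centroid size — so the injected signal lies exactly
in the shape space that per-region GPA recovers. The two-region
rate-ratio test (2:1 injected, recovered within [1.5, 2.7]) depends on
this construction.

Real data differ in ways the generator does not emulate: landmarks are
correlated through anatomy rather than independent in a tangent basis;
digitising error is structured (view angle, scale-bar error), not
isotropic Gaussian; trees are not pure-birth and carry calibration
uncertainty; and shape variation can be large enough that tangent-space
linearity degrades. Passing tests therefore demonstrate the correctness
of the estimators under their own model assumptions, not robustness to
these violations.

## Problem sizes

Oracle tests run on trees of <= 12 tips; parameter- and model-recovery
simulations use 200 tips, 10 traits, 20 replicates; the permutation
calibration uses 200 null datasets of 50 rows with 2000 permutations
each (the permutation statistic is fully vectorised); the end-to-end
recovery uses 10 replicate datasets of 100 tips. These sizes give stable
medians while keeping the complete suite fast.

## Known limitations

* 2D landmarks only; no missing-landmark estimation or object symmetry.
* Single-optimum OU; no multi-optimum or clade-shift models.
* Pooled equal-rate traits; no full p x p rate matrix in the likelihood.
* Semi-landmark tangents are chords between neighbours; strongly curved,
  sparsely sampled curves would need spline tangents.
* Mean standardization of near-zero tangent coordinates is guarded but
  intrinsically awkward; compare standardized and unstandardized runs.
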