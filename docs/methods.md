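# Methods

This note documents the numerical model behind the package, the parameters
that matter, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open.

## Deformation-field representation

Fields live on regular 3D lattices in 0-based voxel-index coordinates and
are stored as displacements d with φ(x) = x + d(x); identity is the zero
array and the additive per-step updates of the integrator are plain vector
additions.  Physical spacing is carried by the grid but only used by
distance-valued metrics (Hausdorff).  Spatial derivatives use
`numpy.gradient` stencils — second-order central differences in the
interior, first-order one-sided differences on boundary faces — and the
*same* stencils back the Jacobian determinant, the divergence and the
smoothness penalty, so trace(∇d) equals div d to machine precision and
`jacobian_loss == 0` iff the strict folding count is zero.  Warping and
composition sample trilinearly with coordinates clamped to the grid bounds;
clamping (rather than extrapolation) avoids manufacturing folds at the
boundary.  Inversion is the standard fixed-point iteration
d⁻¹ ← −d(x + d⁻¹(x)) (default 30 iterations, tolerance 1e-3 voxels) with an
explicit convergence flag; it converges for fields that are diffeomorphic
in practice (min J > 0, moderate amplitude relative to smoothness).

Gaussian smoothing uses a discrete kernel truncated at 4σ with
normalized-convolution edge handling (smoothed values divided by the
smoothed domain indicator), so constants are preserved exactly everywhere —
this is what makes the homotopy field's initial state map to exactly 1.
Resampling by factors of 2 samples output voxel i at input coordinate
i/factor and multiplies displacement components by the factor; downsampling
applies a Gaussian anti-alias pre-filter with σ = (1/factor − 1)/2 (the
scikit-image convention).  An upsample followed by a downsample is an exact
round trip on the original lattice nodes.

## Homotopy control-increment integration

The deformation is integrated over t ∈ [0, 1] in N uniform steps.  Each
step applies

    φₙ = φₙ₋₁ + Δt · u(φₙ₋₁) / h(φₙ₋₁),

with u sampled trilinearly at the deformed positions and h evaluated by
smoothing the h lattice with a normalized Gaussian (bandwidth σ_h, default
2 voxels) and sampling it trilinearly at φ.  The product form "Δt u h" that
a flattened rendering of the update might suggest was rejected: only the
quotient v = u/h makes d/dt log det ∇φ = div v consistent with
det ∇φ = h(x,0)/h(φ,t) under ∂h/∂t = −div u, and the per-step scaling
"Δt/h" reading matches the cascade description.  h evolves by explicit
Euler on the constraint, h ← h − Δt·div(u), with a positivity floor
(default 1e-3) that clips and flags rather than fails; the constraint
residual |div u + Δh/Δt| is exposed per voxel and is zero to round-off by
construction when h is evolved this way, and nonzero for externally
supplied (u, h) pairs.

Forward and backward deformations are integrated as independent pairs from
their own increments, mirroring the symmetric cascade; swapping the two
increment streams swaps the two paths exactly.  The diagnostic
`check_eq5` reports the maximum interior relative error of J against
h(x,0)/h(φ(x)); it is dominated by the first-order time discretization and
trilinear sampling, and does not increase when N doubles on fixed
increments.

Validity regime: the positivity guarantee is a property of the continuous
constraint; discretely it holds when per-step displacement gradients are
small, roughly Δt·‖∇u‖ ≲ 0.5 (a CFL-like bound).  Smooth increments with
amplitude 2 voxels and smoothness σ = 4 voxels at N = 8 sit comfortably
inside it (observed min J ≈ 0.54 over ten seeds).  Volume drift under
divergence-free control scales quadratically with amplitude (it is a
spatial-discretization effect, not a time-step effect), which is why the
volume-preservation check is run in the small-amplitude regime
(amplitude 0.5, drift < 5%).

## Multiscale folding-aware correction (MFDC)

Folding is detected inclusively (J ≤ 0), matching the MFN metric
("non-positive"), so a reported MFN of zero is self-consistent with the
detector.  The procedure:

1. **Fusion.**  A pyramid of the field at ratios 1, 1/2, 1/4, 1/8, 1/16 is
   built by chained anti-aliased halving, each level re-upsampled to full
   resolution (axes ≥ 48 voxels keep all five levels; smaller grids
   truncate with a warning and the missing levels' weight reverts to the
   full-resolution field).  A Gaussian-smoothed folding density ρ (σ_ρ = 2
   voxels) gates the per-voxel weights
   W1 = (1 − sigmoid(k(ρ − τ)))·W_folding + sigmoid(k(ρ − τ))·ε,
   Wr = βᵣ(1 − W1), clamped to [ε, 1] and renormalized to a per-voxel sum
   of exactly 1.  W_folding is not pinned down by the weighting formula
   itself; here it defaults to a Gaussian-smoothed indicator of J > 0 (so
   confidence decays smoothly toward folds) and can be set to the
   constant 1.  Defaults k = 10, τ = 0.1, ε = 1e-3, uniform βᵣ = 0.25.
   Because correction is meant to act only around detected folding, the
   fused field is blended into the input inside a ramped neighborhood of
   the folding set whose radius grows with the outer round; voxels away
   from folds are untouched, which keeps the repair local and provable so
   (changes confined to the folding mask dilated by outer_rounds + 2).

2. **Geometric kernel repair.**  For each remaining folded interior voxel,
   the deformed positions of its 26 neighbors are assembled into a closed
   shell with a fixed triangulation (each cube face's 3×3 point grid split
   into 8 triangles along fixed diagonals, oriented outward in the
   reference lattice).  Each oriented triangle contributes a half-space;
   the kernel is their intersection — the 3D extension of the 2D polygon
   kernel (the star-shape region from which the whole boundary is
   visible).  Feasibility and a representative interior point are computed
   by linear programming as the Chebyshev center (the exact polytope
   centroid would require vertex enumeration; the Chebyshev center is a
   deterministic interior point with maximal clearance, and is documented
   as an approximation of "the centroid of the kernel").  A folded voxel
   with a non-empty kernel is moved there; with an empty kernel, the most
   concave neighbor — operationalized as the neighbor with the largest
   residual from the best-fit affine map of the shell, a scale-invariant
   reading of "coordinate variance" — is shifted fraction η (default 0.5)
   toward its own kernel (or toward its local neighbor centroid).  Folds
   on the boundary shell itself are left to fusion.  The inner loop runs
   until the folding set is empty or its size stops decreasing (at most
   T_max = 50 sweeps).

3. **Fallback.**  If folding stalls above zero, fusion is re-run with τ
   halved — shifting weight toward the coarse levels, which are smooth and
   fold-free in practice — for up to R_max = 5 outer rounds.  The report
   carries initial/final MFN, iteration counts, corrected voxels and a
   `converged` flag; the routine never silently returns a folded field.
   A fold-free input is returned unchanged.

Forward and backward fields are corrected independently.  On seeded folded
fields (48³, initial MFN 68–754 across ten seeds) the procedure reaches
MFN = 0 in 2–4 outer rounds, a few seconds per field on one CPU.

## Losses and metrics

Similarity is mean local windowed NCC (window 9, variance stabilizer 1e-5)
summed over scales with per-scale weights λ1 (a single printed λ1 = 0.8 is
applied uniformly; configurable per scale), with coarse fields upsampled to
full resolution by chained trilinear doubling before warping.  The
stabilizer bounds attainable self-similarity away from exactly 1 and limits
affine invariance to ~1e-4 on low-variance windows.  The Jacobian loss sums
ReLU(−J) over scales and both directions; the smoothness loss sums squared
displacement gradients (identity costs zero — the convention of the common
baselines, which makes the identity a loss minimum); the cycle loss
evaluates NCC of each image against itself warped through φ∘φ⁻¹ and
φ⁻¹∘φ; the constraint loss sums the per-step residual maps.  Default
weights: λ2 = 1e-4, λ3 = 1, λ4 = 0.1, λ5 = 0.1.

Dice is computed per label (background excluded, labels absent from both
volumes excluded from the mean); the Hausdorff distance is the symmetric
maximum (or percentile, e.g. HD95 behind a flag) of surface-voxel
nearest-neighbor distances scaled by grid spacing; SSIM is the standard
local-window formulation (window 7, data range from the inputs) delegated
to scikit-image; MFN counts J ≤ 0 voxels.

## Reference registrar

A desk-scale, non-learned instantiation of the multiscale symmetric
cascade, intended to exercise the integrator's contract rather than to
compete with trained predictors: anti-aliased intensity pyramids stand in
for learned feature pyramids, and a demons-type force

    f = (Y − X∘φ)·∇(X∘φ) / (‖∇(X∘φ)‖² + (Y − X∘φ)² + δ)

(Gaussian-smoothed, σ_force = 2) stands in for the learned increment
predictor.  The control increment is u = N·f so that integrating against
the step length 1/N applies one demons step per cascade stage, with the
per-step displacement Δt·u capped at `step_scale` (default 1 voxel/step)
and the boundary shell zeroed.  The cascade runs L = 5 scales (truncated
where an axis would fall below 3 voxels) with N = 4 steps per scale,
initializes each scale from the ×2-upsampled previous field, computes
backward increments with the same provider on the swapped image pair, and
resets h ≡ 1 at each scale (how h should carry across scales is not
determined by the formulation; restarting keeps each scale's unit-time
integration self-consistent).  MFDC runs on both outputs by default.
Full-resolution NCC is recorded per scale and is non-decreasing on phantom
pairs; a 2-voxel rigid blob shift is recovered to ~0.3 voxel (median over
the blob) at 48³.

## Synthetic data

The generators emulate the statistical structure the method assumes —
globally smooth displacement fields with spatially localized folding — and
are pure functions of their spec (fixed seed ⇒ identical bytes).

- `random_smooth_field`: component-wise Gaussian-smoothed white noise
  (σ_gen, default 4 voxels), attenuated by a smooth sin² taper that is
  exactly zero on the boundary shell and reaches 1 at depth σ_gen, then
  rescaled to a maximum displacement norm of `amplitude`.  The taper is
  smooth rather than a hard boundary zeroing because a one-voxel cutoff of
  a full-amplitude field would itself create a folded ring at the
  boundary, confounding every downstream positivity study.  At amplitude 1
  (σ_gen 4, 32³) the fields are diffeomorphic across seeds; folding
  appears around amplitude ≈ 2.5–3.
- `folded_field`: geometric amplitude escalation (×1.5, with gentle
  back-off) of a seeded smooth field until the non-positive-Jacobian count
  lands in a target range (default 50–5000, bracketing the folding
  severities a deformation predictor typically produces); scattered,
  localized folds — matching the locality claims the correction makes —
  rather than one analytic swirl.
- `divfree_increment`: the curl of a Gaussian-smoothed random vector
  potential multiplied by a window vanishing on a 3-voxel boundary shell;
  taking the curl *after* windowing makes the discrete divergence zero to
  machine precision (central-difference operators commute), strictly
  stronger than a tapered-curl construction.
- `phantom_pair`: a multi-ellipsoid labelled phantom (ellipsoid radii
  12–22% of the volume, intensities 0.5–1.0, plus a smooth background
  texture normalized to std 0.05 so windowed NCC has usable variance
  everywhere) deformed by a seeded smooth field; the pair is related by a
  known diffeomorphism, labels warped nearest-neighbor.

None of this emulates anatomy, acquisition noise, bias fields, or
inter-subject variability; passing tests demonstrate the mechanics of the
constraint and the correction on the deformation statistics they assume,
not registration accuracy on clinical data.

## Problem sizes and numerical choices

Test and acceptance runs use 32³ grids for integrator studies (N = 8
steps, ten seeds) and 48³ grids for correction and registration studies —
the smallest sizes that hold a full five-level pyramid and leave a
meaningful interior.  LP feasibility uses the HiGHS solver with a
positive-radius threshold of 1e-9; degenerate (zero-area) shell faces are
skipped with a warning; inversion defaults to 30 iterations at tol 1e-3
voxels; the NCC stabilizer is 1e-5; the homotopy floor is 1e-3.  The
folded-field escalation raises an explicit error if the target folding
range is not reached within 20 escalations.

## Known limitations

- The homotopy step is explicit Euler; very large per-step increments
  (Δt·‖∇u‖ approaching 1) can crash h into its floor and stall or distort
  the flow.  The registrar's step cap keeps it in regime; externally
  supplied increments are the caller's responsibility.
- The geometric repair skips boundary voxels (no full 26-neighborhood);
  boundary folds rely on fusion.
- `mfdc_correct` can in principle exhaust R_max without reaching MFN = 0
  (reported via `converged=False`); not observed on the tested severities.
- The registrar is a demonstration driver: intensity demons forces, no
  learned features, no multi-modal similarity.
- World-affine resampling across differently oriented grids is out of
  scope; volumes are assumed axis-aligned with voxel-unit fields.
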