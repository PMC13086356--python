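# mfdc — topology-preserving deformation fields

Tools for diffeomorphic deformable image registration with an explicit,
repairable topology guarantee.  Deformable registration estimates a dense
deformation φ(x) = x + d(x) aligning a moving volume X to a fixed volume Y;
a physically meaningful φ must be invertible, which numerically means its
Jacobian determinant J(x) = det ∇φ(x) stays strictly positive.  Learned and
iterative predictors alike can violate this locally ("folding", J ≤ 0).

This package implements two complementary mechanisms around that problem:

1. **Homotopy control-increment integration.**  Instead of a stationary
   velocity field with scaling-and-squaring, the deformation is integrated
   over pseudo-time t ∈ [0, 1] by per-step control increments u with a
   positive scalar homotopy field h (h ≡ 1 at t = 0) bookkeeping volume
   change under the constraint

       div(u) + ∂h/∂t = 0 in the interior,   u = 0 on ∂Ω,

   which yields det ∇φ(x, t) = h(x, 0) / h(φ(x, t), t) > 0 — positivity of
   h certifies local invertibility at every step.  The update is
   φₙ = φₙ₋₁ + Δt·u(φₙ₋₁)/h(φₙ₋₁).

2. **Multiscale Folding-aware Deformation Correction (MFDC).**  A
   plug-and-play repair stage for *any* displacement field: a
   folding-density-gated fusion of the field with anti-aliased coarse
   copies of itself (weights W1 and Wr = βᵣ(1 − W1), normalized to sum 1
   per voxel), followed by a geometric repair loop that tests each folded
   voxel's deformed 26-neighbor shell against the polygon-kernel
   (star-shape) criterion and projects the voxel into the kernel's
   Chebyshev center when it is non-empty, or nudges the most concave
   neighbor toward feasibility when it is not.  The procedure either
   reaches a folding count (MFN) of zero or reports non-convergence
   explicitly.

Also included: the associated loss suite (windowed NCC similarity over
scales, ReLU Jacobian penalty, displacement-gradient smoothness, cycle
consistency, control-increment constraint residual), quality metrics
(Dice, Hausdorff distance, SSIM, MFN), a non-learned multiscale symmetric
registration driver (demons-type forces driving the homotopy integrator),
and seeded synthetic generators for fields, folded fields, divergence-free
increments and phantom image/label pairs.

Intended users: researchers in medical image registration who want a
testable, framework-independent implementation of the constraint mechanics
and of the correction module, e.g. to post-process deformation fields
predicted by their own networks (NIfTI in, NIfTI out).

## Worked example

Remove all folding from a deliberately folded synthetic field:

```python
from mfdc import GeneratorSpec, folded_field, mfdc_correct, jacobian_determinant

spec = GeneratorSpec(shape=(48, 48, 48), amplitude=3.0, sigma_gen=4.0,
                     seed=2, target_mfn=(50, 5000))
field, mfn_before = folded_field(spec)
print(f"initial folded voxels (MFN): {mfn_before}")
print(f"min Jacobian determinant before: {jacobian_determinant(field).values.min():.3f}")

corrected, report = mfdc_correct(field)
print(f"final MFN: {report.mfn_final}  (converged={report.converged})")
print(f"fusion rounds: {report.outer_rounds}, geometric repair sweeps: {report.inner_iterations}")
print(f"min Jacobian determinant after: {jacobian_determinant(corrected).values.min():.3f}")
```

Output:

```
initial folded voxels (MFN): 720
min Jacobian determinant before: -0.782
final MFN: 0  (converged=True)
fusion rounds: 3, geometric repair sweeps: 8
min Jacobian determinant after: 0.001
```

The generator escalated a smooth random field until 720 voxels had
non-positive Jacobian determinant (a locally folded, non-invertible map);
after three fusion rounds and eight geometric repair sweeps every voxel is
orientation-preserving again, and changes are confined to a small
neighborhood of the original folds.

The same operation from the shell:

```bash
mfdc simulate --kind folded --shape 48,48,48 --seed 2 --amplitude 3.0 --out /tmp/f
mfdc correct --in /tmp/f_field.nii.gz --out /tmp/fixed.nii.gz --report /tmp/report.json
```

Registration of a phantom pair, with correction applied to both outputs:

```bash
mfdc simulate --kind phantom --shape 48,48,48 --seed 3 --out /tmp/p
mfdc register --moving /tmp/p_X.nii.gz --fixed /tmp/p_Y.nii.gz \
    --out-fwd /tmp/fwd.nii.gz --out-bwd /tmp/bwd.nii.gz --report /tmp/reg.json
mfdc evaluate --fixed /tmp/p_Y.nii.gz --moving /tmp/p_X.nii.gz \
    --field /tmp/fwd.nii.gz --labels-fixed /tmp/p_labelsY.nii.gz \
    --labels-moving /tmp/p_labelsX.nii.gz --report /tmp/metrics.json
```

Displacement fields are stored as NIfTI with a trailing vector dimension
(X×Y×Z×1×3, vector intent; the plain X×Y×Z×3 dialect is also read) and are
in **voxel units**, not millimetres.

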