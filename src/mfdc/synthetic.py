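"""Seeded synthetic inputs: smooth fields, folded fields, divergence-free
control increments, and phantom image/label pairs.

These generators emulate the statistical structure the correction method
assumes about predicted deformation fields — globally smooth displacements
with spatially localized folding — without any anatomical realism.  All
generators are pure functions of their spec: a fixed seed reproduces the
output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .correction import folding_set
from .fields import (
    DisplacementField,
    Grid,
    ScalarMap,
    gaussian_smooth,
    invert,
    warp_volume,
)
from .homotopy import ControlIncrement


@dataclass
class GeneratorSpec:
    """Shared knobs of the generators.

    amplitude : max displacement magnitude in voxels.
    sigma_gen : Gaussian smoothness of the underlying noise (voxels);
        larger values give smoother, lower-frequency fields.
    target_mfn : for :func:`folded_field`, the acceptable range of initial
        folding counts.
    """

    shape: tuple = (32, 32, 32)
    amplitude: float = 1.0
    sigma_gen: float = 4.0
    seed: int = 0
    target_mfn: tuple | None = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        self.shape = tuple(int(s) for s in self.shape)

    @property
    def grid(self) -> Grid:
        return Grid(self.shape)


def _boundary_distance(shape) -> np.ndarray:
    """Per-voxel distance (in voxels) to the boundary shell."""
    inner = np.zeros(shape, dtype=bool)
    inner[1:-1, 1:-1, 1:-1] = True
    return ndimage.distance_transform_edt(inner)


def _taper(shape, width: float) -> np.ndarray:
    """Smooth window: exactly 0 on the boundary shell, 1 at depth >= width."""
    d = _boundary_distance(shape)
    t = np.clip(d / max(width, 1.0), 0.0, 1.0)
    return np.sin(0.5 * np.pi * t) ** 2


def random_smooth_field(spec: GeneratorSpec) -> DisplacementField:
    """Gaussian-smoothed white-noise displacement, boundary-zeroed.

    White-noise vectors are smoothed component-wise with ``sigma_gen``,
    attenuated by a smooth taper that vanishes on the boundary shell, and
    rescaled so the maximum displacement norm equals ``amplitude``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    d = rng.standard_normal((3,) + spec.shape)
    d = gaussian_smooth(d, spec.sigma_gen)
    d *= _taper(spec.shape, spec.sigma_gen)[None]
    norms = np.linalg.norm(d, axis=0)
    peak = norms.max()
    if peak > 0 and spec.amplitude > 0:
        d *= spec.amplitude / peak
    else:
        d[:] = 0.0
    return DisplacementField(grid, d)


def folded_field(spec: GeneratorSpec, max_escalations: int = 20):
    """A deliberately folded field with an initial MFN in ``target_mfn``.

    The amplitude of a seeded smooth field is escalated geometrically
    (factor 1.5) until the non-positive-Jacobian count lands in the target
    range.  Returns ``(field, mfn)``.
    """
    lo, hi = spec.target_mfn if spec.target_mfn else (50, 5000)
    if (lo, hi) == (0, 0):
        base = random_smooth_field(spec)
        return base, folding_set(base).count
    amp = spec.amplitude
    for _ in range(max_escalations):
        trial = GeneratorSpec(
            shape=spec.shape, amplitude=amp, sigma_gen=spec.sigma_gen, seed=spec.seed
        )
        field = random_smooth_field(trial)
        count = folding_set(field).count
        if lo <= count <= hi:
            return field, count
        if count > hi:
            amp /= 1.2  # overshot: back off gently
        else:
            amp *= 1.5
    raise RuntimeError(
        f"could not reach target MFN range {(lo, hi)} within {max_escalations} escalations"
    )


def divfree_increment(spec: GeneratorSpec) -> ControlIncrement:
    """Divergence-free control increment: the curl of a tapered potential.

    The vector potential (smoothed noise) is multiplied by a window that
    vanishes on a 3-voxel boundary shell *before* the curl is taken; since
    discrete central-difference operators commute, div(curl A) is zero to
    machine precision, and the increment vanishes on the boundary.
    """
    rng = np.random.default_rng(spec.seed)
    A = gaussian_smooth(rng.standard_normal((3,) + spec.shape), spec.sigma_gen)
    d = _boundary_distance(spec.shape)
    w = np.clip((d - 2.0) / max(spec.sigma_gen, 1.0), 0.0, 1.0)
    w = np.sin(0.5 * np.pi * w) ** 2
    A = A * w[None]
    g = lambda f, ax: np.gradient(f, axis=ax, edge_order=1)
    u = np.stack(
        [
            g(A[2], 1) - g(A[1], 2),
            g(A[0], 2) - g(A[2], 0),
            g(A[1], 0) - g(A[0], 1),
        ]
    )
    norms = np.linalg.norm(u, axis=0)
    peak = norms.max()
    if peak > 0 and spec.amplitude > 0:
        u *= spec.amplitude / peak
    else:
        u[:] = 0.0
    boundary = ~spec.grid.interior
    u[:, boundary] = 0.0
    return ControlIncrement(spec.grid, u)


def phantom_pair(spec: GeneratorSpec, n_structures: int = 4):
    """Multi-ellipsoid phantom pair related by a known smooth deformation.

    X is a smooth image with ``n_structures`` labelled ellipsoids plus a
    faint smooth texture (so windowed NCC has gradients everywhere);
    phi_true is a seeded smooth field (diffeomorphic by construction at
    moderate amplitude); Y = X ∘ phi_true^{-1} with labels warped
    nearest-neighbor.  Returns (X, Y, labels_X, labels_Y, phi_true).
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    shape = np.array(spec.shape, dtype=float)
    coords = grid.coords()
    intensity = np.zeros(spec.shape)
    labels = np.zeros(spec.shape, dtype=int)
    for lab in range(1, n_structures + 1):
        center = shape * rng.uniform(0.25, 0.75, size=3)
        radii = shape * rng.uniform(0.12, 0.22, size=3)
        q = sum(((coords[i] - center[i]) / radii[i]) ** 2 for i in range(3))
        inside = q <= 1.0
        labels[inside] = lab
        intensity[inside] = 0.5 + 0.5 * lab / n_structures
    intensity = gaussian_smooth(intensity, 1.0)
    # faint smooth texture, normalized so every local window has usable
    # variance for windowed similarity measures
    tex = gaussian_smooth(rng.standard_normal(spec.shape), 2.0)
    intensity += 0.05 * tex / tex.std()

    phi_true = random_smooth_field(
        GeneratorSpec(
            shape=spec.shape, amplitude=spec.amplitude, sigma_gen=spec.sigma_gen,
            seed=spec.seed + 10_000,
        )
    )
    X = ScalarMap(grid, intensity)
    labels_X = ScalarMap(grid, labels.astype(float))
    if spec.amplitude == 0:
        return X, ScalarMap(grid, intensity.copy()), labels_X, ScalarMap(grid, labels.astype(float)), phi_true
    phi_inv = invert(phi_true, max_iter=50, tol=1e-4).field
    Y = warp_volume(X, phi_inv)
    labels_Y = warp_volume(labels_X, phi_inv, interp="nearest")
    return X, Y, labels_X, labels_Y, phi_true
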