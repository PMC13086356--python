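"""Deformation-field algebra on regular 3D lattices.

All fields live on a :class:`Grid` in 0-based voxel-index coordinates.  A
deformation is stored as a displacement ``d`` with ``phi(x) = x + d(x)``;
displacements map voxel coordinates to voxel coordinates, so composing,
warping and inverting never touch physical spacing (spacing only matters for
distance-valued metrics such as the Hausdorff distance).

Finite differences use :func:`numpy.gradient` stencils: second-order central
differences on interior voxels and first-order one-sided differences on the
boundary faces.  The same stencils back the Jacobian determinant, the
divergence and the smoothness penalty so that identities between them hold
to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Operands live on different grids."""


class InvalidFieldError(ValueError):
    """Field contains non-finite values or has the wrong shape."""


@dataclass(frozen=True)
class Grid:
    """Regular 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; every axis must be >= 3 so central differences
        have an interior.
    spacing : tuple of float
        Physical length units per voxel (default isotropic 1.0).
    """

    shape: tuple
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise InvalidFieldError("Grid is 3D: need 3 shape and 3 spacing entries")
        if any(s < 3 for s in shape):
            raise InvalidFieldError(f"every axis must be >= 3, got {shape}")
        if any(s <= 0 for s in spacing):
            raise InvalidFieldError(f"spacing must be positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def interior(self):
        """Boolean mask of interior (non-boundary) voxels."""
        m = np.zeros(self.shape, dtype=bool)
        m[1:-1, 1:-1, 1:-1] = True
        return m

    def coords(self):
        """Voxel-index coordinate arrays, shape (3, *shape)."""
        return np.stack(
            np.meshgrid(*(np.arange(s, dtype=float) for s in self.shape), indexing="ij")
        )


def _check_lattice(grid: Grid, arr: np.ndarray, ncomp: int | None):
    expected = grid.shape if ncomp is None else (ncomp,) + grid.shape
    if arr.shape != expected:
        raise InvalidFieldError(f"lattice shape {arr.shape} != expected {expected}")
    if not np.all(np.isfinite(arr)):
        raise InvalidFieldError("lattice contains non-finite values")


@dataclass
class ScalarMap:
    """Scalar lattice on a grid (image intensities, J maps, h, rho, ...)."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_lattice(self.grid, self.values, None)


@dataclass
class DisplacementField:
    """Dense displacement d on a grid; the deformation is phi(x) = x + d(x).

    ``d`` has shape (3, X, Y, Z) in voxel units.
    """

    grid: Grid
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        _check_lattice(self.grid, self.d, 3)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.grid, self.d.copy())

    def phi(self) -> np.ndarray:
        """Absolute deformed coordinates, shape (3, X, Y, Z)."""
        return self.grid.coords() + self.d


@dataclass
class InversionResult:
    field: DisplacementField
    converged: bool
    iterations: int
    max_update: float


def identity_field(grid: Grid) -> DisplacementField:
    return DisplacementField(grid, np.zeros((3,) + grid.shape))


def _same_grid(a, b):
    if a.grid.shape != b.grid.shape:
        raise GridMismatchError(f"grids differ: {a.grid.shape} vs {b.grid.shape}")


def _grad(component: np.ndarray, axis: int) -> np.ndarray:
    # np.gradient: central differences interior, one-sided first order at faces
    return np.gradient(component, axis=axis, edge_order=1)


def displacement_jacobian(d: np.ndarray) -> np.ndarray:
    """Per-voxel gradient tensor of a displacement, shape (3, 3, X, Y, Z)."""
    return np.stack([np.stack([_grad(d[i], j) for j in range(3)]) for i in range(3)])


def jacobian_determinant(field: DisplacementField) -> ScalarMap:
    """Per-voxel Jacobian determinant J(x) = det(I + grad d(x)).

    A strictly positive J everywhere is the numerical evidence that the
    deformation is locally invertible (orientation-preserving); J <= 0
    marks folding.
    """
    g = displacement_jacobian(field.d)
    for i in range(3):
        g[i, i] += 1.0
    det = (
        g[0, 0] * (g[1, 1] * g[2, 2] - g[1, 2] * g[2, 1])
        - g[0, 1] * (g[1, 0] * g[2, 2] - g[1, 2] * g[2, 0])
        + g[0, 2] * (g[1, 0] * g[2, 1] - g[1, 1] * g[2, 0])
    )
    return ScalarMap(field.grid, det)


def divergence(v: DisplacementField) -> ScalarMap:
    """div v = sum_i dv_i/dx_i with the same stencils as the Jacobian."""
    vals = sum(_grad(v.d[i], i) for i in range(3))
    return ScalarMap(v.grid, vals)


def _sample(lattice: np.ndarray, coords: np.ndarray, order: int) -> np.ndarray:
    """Sample a scalar lattice at fractional coords (3, ...), clamped to bounds."""
    clamped = np.empty_like(coords)
    for ax in range(3):
        clamped[ax] = np.clip(coords[ax], 0, lattice.shape[ax] - 1)
    return ndimage.map_coordinates(lattice, clamped, order=order, mode="nearest")


def warp_volume(volume: ScalarMap, field: DisplacementField, interp: str = "trilinear") -> ScalarMap:
    """Resample ``volume`` through the deformation: out(x) = volume(x + d(x)).

    Use ``interp='nearest'`` for integer label volumes.
    """
    _same_grid(volume, field)
    order = {"trilinear": 1, "nearest": 0}.get(interp)
    if order is None:
        raise ValueError(f"unknown interp {interp!r}")
    out = _sample(volume.values, field.phi(), order)
    if interp == "nearest":
        out = out.astype(volume.values.dtype)
    return ScalarMap(field.grid, out)


def compose(a: DisplacementField, b: DisplacementField) -> DisplacementField:
    """Composition a∘b: the field of x -> a(b(x)).

    d_out(x) = d_b(x) + d_a sampled trilinearly at x + d_b(x).
    """
    _same_grid(a, b)
    coords = b.phi()
    d_out = b.d + np.stack([_sample(a.d[i], coords, 1) for i in range(3)])
    return DisplacementField(a.grid, d_out)


def invert(field: DisplacementField, max_iter: int = 30, tol: float = 1e-3) -> InversionResult:
    """Fixed-point inversion: d_inv <- -d(x + d_inv(x)).

    Converges for fields that are diffeomorphic in practice (min J > 0 and
    moderate amplitude).  Non-convergence is flagged, not raised, since the
    caller may still find the approximate inverse useful.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    coords0 = field.grid.coords()
    d_inv = np.zeros_like(field.d)
    max_update = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        coords = coords0 + d_inv
        new = -np.stack([_sample(field.d[i], coords, 1) for i in range(3)])
        max_update = float(np.max(np.abs(new - d_inv)))
        d_inv = new
        if max_update < tol:
            break
    return InversionResult(
        DisplacementField(field.grid, d_inv),
        converged=max_update < tol,
        iterations=it,
        max_update=max_update,
    )


def gaussian_smooth(obj, sigma: float):
    """Separable discrete Gaussian with edge renormalization.

    The kernel is truncated at 4*sigma and normalized; near the boundary the
    result is divided by the smoothed indicator of the domain (normalized
    convolution), so a constant lattice is preserved exactly everywhere.
    sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")

    def smooth_arr(arr):
        if sigma == 0:
            return arr.copy()
        num = ndimage.gaussian_filter(arr, sigma, mode="constant", cval=0.0, truncate=4.0)
        den = ndimage.gaussian_filter(
            np.ones_like(arr), sigma, mode="constant", cval=0.0, truncate=4.0
        )
        return num / den

    if isinstance(obj, ScalarMap):
        return ScalarMap(obj.grid, smooth_arr(obj.values))
    if isinstance(obj, DisplacementField):
        return DisplacementField(obj.grid, np.stack([smooth_arr(c) for c in obj.d]))
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 4 and arr.shape[0] == 3:
        return np.stack([smooth_arr(c) for c in arr])
    return smooth_arr(arr)


def _resample_lattice(arr: np.ndarray, out_shape: tuple, scale: tuple, order: int = 1) -> np.ndarray:
    """Sample ``arr`` on an ``out_shape`` lattice; out voxel i maps to in coord i/scale."""
    axes = [np.arange(n, dtype=float) / s for n, s in zip(out_shape, scale)]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))
    return _sample(arr, coords, order)


def resample(obj, factor: float, anti_alias: bool = True):
    """Resample by a factor of 2 or 1/2 (chain for other powers of two).

    Output voxel i samples input coordinate i/factor (trilinear), so an
    upsample followed by a downsample is an exact round trip on the original
    lattice nodes.  Displacement components are multiplied by ``factor``
    (voxel-coordinate rescaling).  Downsampling applies a Gaussian
    anti-alias pre-filter with sigma = (1/factor - 1)/2 (the scikit-image
    convention) when ``anti_alias`` is on.
    """
    if not np.isclose(factor, 2.0) and not np.isclose(factor, 0.5):
        raise ValueError("factor must be 2 or 1/2; chain calls for other powers of two")

    grid = obj.grid
    out_shape = tuple(int(round(n * factor)) for n in grid.shape)
    if any(n < 3 for n in out_shape):
        raise InvalidFieldError(f"resampled axis below 3: {out_shape}")
    out_grid = Grid(out_shape, tuple(sp / factor for sp in grid.spacing))
    scale = (factor,) * 3

    aa_sigma = (1.0 / factor - 1.0) / 2.0 if factor < 1 else 0.0
    if isinstance(obj, ScalarMap):
        arr = obj.values
        if aa_sigma > 0 and anti_alias:
            arr = gaussian_smooth(arr, aa_sigma)
        return ScalarMap(out_grid, _resample_lattice(arr, out_shape, scale))
    if isinstance(obj, DisplacementField):
        d = obj.d
        if aa_sigma > 0 and anti_alias:
            d = gaussian_smooth(d, aa_sigma)
        comps = [factor * _resample_lattice(d[i], out_shape, scale) for i in range(3)]
        return DisplacementField(out_grid, np.stack(comps))
    raise TypeError(f"cannot resample {type(obj)!r}")


def resample_to_shape(obj, out_shape: tuple, anti_alias: bool = True):
    """Resample to an explicit target shape (per-axis scale n_out/n_in).

    Displacement components are rescaled per axis by the same factors.  Used
    where exact shape agreement matters (image pyramids, cross-scale field
    initialization) and the shapes are not exact powers-of-two multiples.
    """
    out_shape = tuple(int(s) for s in out_shape)
    if any(n < 3 for n in out_shape):
        raise InvalidFieldError(f"target axis below 3: {out_shape}")
    grid = obj.grid
    scale = tuple(o / i for o, i in zip(out_shape, grid.shape))
    out_grid = Grid(out_shape, tuple(sp / s for sp, s in zip(grid.spacing, scale)))
    aa_sigma = max((1.0 / min(scale) - 1.0) / 2.0, 0.0) if min(scale) < 1 else 0.0

    if isinstance(obj, ScalarMap):
        arr = obj.values
        if aa_sigma > 0 and anti_alias:
            arr = gaussian_smooth(arr, aa_sigma)
        return ScalarMap(out_grid, _resample_lattice(arr, out_shape, scale))
    if isinstance(obj, DisplacementField):
        d = obj.d
        if aa_sigma > 0 and anti_alias:
            d = gaussian_smooth(d, aa_sigma)
        comps = [scale[i] * _resample_lattice(d[i], out_shape, scale) for i in range(3)]
        return DisplacementField(out_grid, np.stack(comps))
    raise TypeError(f"cannot resample {type(obj)!r}")
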