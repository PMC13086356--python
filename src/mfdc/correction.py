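"""Multiscale Folding-aware Deformation Correction (MFDC).

A plug-and-play repair stage for dense deformation fields of any
provenance.  Folding — voxels whose Jacobian determinant is non-positive —
is removed in two synergistic passes:

1. *Folding-aware multiscale fusion.*  A pyramid of progressively
   anti-aliased, coarser copies of the field is built and re-upsampled to
   full resolution.  A Gaussian-smoothed folding-density map rho modulates
   per-voxel mixing weights so that coarse (smooth) levels dominate where
   folding is dense and the full-resolution field is kept where it is
   reliable.  Following the locality of the method (correction is triggered
   only around detected folding voxels), the fused field is blended into
   the input only within a ramped neighborhood of the folding set.

2. *Geometry-based kernel repair.*  Each remaining folded voxel is tested
   against the star-shape (polygon kernel) criterion on its deformed
   26-neighbor shell: if the intersection of the half-spaces carried by the
   shell's oriented faces is non-empty, moving the voxel's deformed
   position into that kernel yields a locally fold-free configuration.
   Feasibility and a representative interior point (the Chebyshev center)
   are obtained by linear programming.  When the kernel is empty, the most
   concave neighbor — the one with the largest residual from the best-fit
   local affine map — is nudged toward its own kernel.

If the folding count stalls above zero, fusion is re-run with a halved
density threshold (shifting weight toward coarse levels), up to a bounded
number of outer rounds.  The procedure either reaches a folding count of
zero or reports non-convergence explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.optimize import linprog
from scipy.special import expit

from .fields import (
    DisplacementField,
    Grid,
    GridMismatchError,
    ScalarMap,
    gaussian_smooth,
    jacobian_determinant,
    resample,
    resample_to_shape,
)

#: Coarse pyramid ratios, finest to coarsest (r = 1 is the field itself).
COARSE_RATIOS = (0.5, 0.25, 0.125, 0.0625)


class ConfigError(ValueError):
    pass


class BoundaryVoxelError(ValueError):
    """Geometric repair needs all 26 neighbors; boundary folds are fused only."""


class EmptyKernelError(ValueError):
    pass


@dataclass
class MFDCConfig:
    """Tunables of the correction procedure.

    k : sigmoid slope of the density gate (unitless).
    tau : folding-density threshold at which coarse mixing takes over.
    eps : floor kept on the full-resolution weight inside dense folding.
    beta : mixing coefficients of the four coarse levels (must sum to 1).
    sigma_rho : bandwidth (voxels) of the folding-density smoothing; also
        used for the fold-aware confidence weight.
    T_max : max inner geometric-repair iterations per fusion round.
    R_max : max outer fusion rounds (tau is halved between rounds).
    eta : fraction of the way a concave neighbor is shifted toward its
        local kernel when the center's kernel is empty.
    w_folding : 'smoothed' for a Gaussian-smoothed indicator of J > 0,
        or 'one' for the constant 1.
    """

    k: float = 10.0
    tau: float = 0.1
    eps: float = 1e-3
    beta: tuple = (0.25, 0.25, 0.25, 0.25)
    sigma_rho: float = 2.0
    T_max: int = 50
    R_max: int = 5
    eta: float = 0.5
    w_folding: str = "smoothed"

    def __post_init__(self):
        if self.k <= 0 or self.tau < 0 or not (0 < self.eps < 1):
            raise ConfigError("need k > 0, tau >= 0, 0 < eps << 1")
        beta = tuple(float(b) for b in self.beta)
        if len(beta) != 4 or any(b < 0 for b in beta) or abs(sum(beta) - 1.0) > 1e-12:
            raise ConfigError("beta must be 4 nonnegative coefficients summing to 1")
        if self.T_max < 1 or self.R_max < 1 or not (0 < self.eta <= 1):
            raise ConfigError("need T_max >= 1, R_max >= 1, 0 < eta <= 1")
        if self.w_folding not in ("smoothed", "one"):
            raise ConfigError("w_folding must be 'smoothed' or 'one'")
        self.beta = beta


@dataclass
class FoldingMap:
    grid: Grid
    mask: np.ndarray
    count: int


@dataclass
class FusionWeights:
    W1: ScalarMap
    Wr: dict  # ratio -> ScalarMap


@dataclass
class KernelRegion:
    nonempty: bool
    point: np.ndarray | None = None
    radius: float | None = None


@dataclass
class LocalConfig:
    center: tuple
    neighbor_positions: np.ndarray  # (26, 3) deformed positions
    faces: np.ndarray  # (n_faces, 3) indices into the 26 offsets


@dataclass
class FoldingReport:
    mfn_initial: int
    mfn_final: int
    inner_iterations: int = 0
    outer_rounds: int = 0
    corrected_voxels: list = dc_field(default_factory=list)
    converged: bool = False
    mfn_history: list = dc_field(default_factory=list)

    def to_dict(self):
        return {
            "mfn_initial": self.mfn_initial,
            "mfn_final": self.mfn_final,
            "inner_iterations": self.inner_iterations,
            "outer_rounds": self.outer_rounds,
            "n_corrected_voxels": len(self.corrected_voxels),
            "corrected_voxels": [list(map(int, v)) for v in self.corrected_voxels],
            "converged": self.converged,
            "mfn_history": self.mfn_history,
        }


# ---------------------------------------------------------------------------
# 26-neighbor shell geometry
# ---------------------------------------------------------------------------

def _build_shell():
    """Reference 26-offset list and fixed outward triangulation of the shell.

    The 3x3x3 shell (minus the center) is triangulated face by cube face:
    each of the six faces carries a 3x3 point grid split into 4 quads, each
    quad split along a fixed diagonal into 2 triangles, oriented so the
    normal points away from the center in the undeformed lattice.
    """
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    index = {off: n for n, off in enumerate(offsets)}
    tris = []
    for axis in range(3):
        for sign in (-1, 1):
            others = [a for a in range(3) if a != axis]
            for a in (-1, 0):
                for b in (-1, 0):
                    quad = []
                    for da, db in ((0, 0), (1, 0), (1, 1), (0, 1)):
                        off = [0, 0, 0]
                        off[axis] = sign
                        off[others[0]] = a + da
                        off[others[1]] = b + db
                        quad.append(index[tuple(off)])
                    tris.append((quad[0], quad[1], quad[2]))
                    tris.append((quad[0], quad[2], quad[3]))
    offsets = np.array(offsets, dtype=float)
    oriented = []
    for t in tris:
        p0, p1, p2 = offsets[list(t)]
        n = np.cross(p1 - p0, p2 - p0)
        centroid = (p0 + p1 + p2) / 3.0
        # outward: normal agrees with the direction away from the center
        if np.dot(n, centroid) < 0:
            t = (t[0], t[2], t[1])
        oriented.append(t)
    return offsets, np.array(oriented, dtype=int)


SHELL_OFFSETS, SHELL_FACES = _build_shell()


# ---------------------------------------------------------------------------
# Folding detection and fusion
# ---------------------------------------------------------------------------

def folding_set(phi: DisplacementField, inclusive: bool = True) -> FoldingMap:
    """Voxels with non-positive (inclusive, default) or negative Jacobian.

    The inclusive convention matches the MFN metric ("non-positive"), so a
    reported MFN of zero is self-consistent with the detector.
    """
    J = jacobian_determinant(phi).values
    mask = (J <= 0) if inclusive else (J < 0)
    return FoldingMap(phi.grid, mask, int(mask.sum()))


def folding_density(fm: FoldingMap, sigma_rho: float) -> ScalarMap:
    """Gaussian-smoothed folding indicator, values in [0, 1]."""
    if sigma_rho <= 0:
        raise ValueError("sigma_rho must be positive")
    vals = gaussian_smooth(fm.mask.astype(float), sigma_rho)
    return ScalarMap(fm.grid, np.clip(vals, 0.0, 1.0))


def fusion_weights(rho: ScalarMap, J: ScalarMap, cfg: MFDCConfig) -> FusionWeights:
    """Density-gated per-voxel mixing weights.

    W1 = (1 - sigmoid(k (rho - tau))) * Wfolding + sigmoid(k (rho - tau)) * eps
    Wr = beta_r (1 - W1)

    with Wfolding either a Gaussian-smoothed indicator of J > 0 (confidence
    drops smoothly near folds) or the constant 1.  Weights are clamped to
    [eps, 1] and renormalized so the per-voxel sum is exactly 1.
    """
    s = expit(cfg.k * (rho.values - cfg.tau))
    if cfg.w_folding == "smoothed":
        w_fold = gaussian_smooth((J.values > 0).astype(float), cfg.sigma_rho)
    else:
        w_fold = np.ones_like(rho.values)
    W1 = (1.0 - s) * w_fold + s * cfg.eps
    W1 = np.clip(W1, cfg.eps, 1.0)
    Wr = {r: b * (1.0 - W1) for r, b in zip(COARSE_RATIOS, cfg.beta)}
    total = W1 + sum(Wr.values())
    W1 = W1 / total
    Wr = {r: w / total for r, w in Wr.items()}
    grid = rho.grid
    return FusionWeights(
        W1=ScalarMap(grid, W1), Wr={r: ScalarMap(grid, w) for r, w in Wr.items()}
    )


def build_pyramid(phi: DisplacementField, anti_alias: bool = True) -> dict:
    """Multiscale copies of the field at ratios 1, 1/2, 1/4, 1/8, 1/16.

    Each coarse level is produced by chained anti-aliased halving and then
    re-upsampled to the full-resolution grid, so all returned fields share
    the input grid.  Levels whose axes would fall below 3 voxels are
    dropped with a warning (all axes >= 48 keeps the full 5-level pyramid).
    """
    pyramid = {1.0: phi}
    current = phi
    for r in COARSE_RATIOS:
        if any(int(round(n * 0.5)) < 3 for n in current.grid.shape):
            warnings.warn(f"pyramid truncated before ratio {r}: axis below 3 voxels")
            break
        current = resample(current, 0.5, anti_alias=anti_alias)
        pyramid[r] = resample_to_shape(current, phi.grid.shape, anti_alias=False)
    return pyramid


def fuse(pyramid: dict, weights: FusionWeights) -> DisplacementField:
    """Per-voxel convex combination of the pyramid levels.

    Coarse levels missing from a truncated pyramid donate their weight to
    the full-resolution field so the combination stays convex.
    """
    full = pyramid[1.0]
    grid = full.grid
    if weights.W1.grid.shape != grid.shape:
        raise GridMismatchError("weights and pyramid grids differ")
    W1 = weights.W1.values.copy()
    for r, w in weights.Wr.items():
        if r not in pyramid:
            W1 = W1 + w.values
    d = W1[None] * full.d
    for r, w in weights.Wr.items():
        if r in pyramid:
            d = d + w.values[None] * pyramid[r].d
    return DisplacementField(grid, d)


# ---------------------------------------------------------------------------
# Geometry-based kernel repair
# ---------------------------------------------------------------------------

def local_configuration(phi: DisplacementField, x) -> LocalConfig:
    """Deformed 26-neighbor shell of an interior voxel with its triangulation."""
    x = tuple(int(v) for v in x)
    shape = phi.grid.shape
    if any(c < 1 or c >= s - 1 for c, s in zip(x, shape)):
        raise BoundaryVoxelError(f"voxel {x} has no full 26-neighborhood")
    base = np.array(x, dtype=float)
    idx = (SHELL_OFFSETS + base).astype(int)
    positions = base + SHELL_OFFSETS + phi.d[:, idx[:, 0], idx[:, 1], idx[:, 2]].T
    return LocalConfig(center=x, neighbor_positions=positions, faces=SHELL_FACES)


def _chebyshev_lp(normals: np.ndarray, offsets: np.ndarray, lo, hi) -> KernelRegion:
    """Chebyshev center of {p : normals @ p <= offsets} within a box."""
    dim = normals.shape[1]
    norms = np.linalg.norm(normals, axis=1)
    keep = norms > 1e-12
    if not np.all(keep):
        warnings.warn("degenerate (zero-area) faces skipped in kernel construction")
    normals, offsets, norms = normals[keep], offsets[keep], norms[keep]
    if normals.shape[0] == 0:
        return KernelRegion(nonempty=False)
    A = np.hstack([normals / norms[:, None], np.ones((normals.shape[0], 1))])
    b = offsets / norms
    c = np.zeros(dim + 1)
    c[-1] = -1.0  # maximize the inscribed radius
    bounds = [(float(l), float(h)) for l, h in zip(lo, hi)] + [(0, None)]
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if not res.success or res.x[-1] <= 1e-9:
        return KernelRegion(nonempty=False)
    return KernelRegion(nonempty=True, point=res.x[:dim].copy(), radius=float(res.x[-1]))


def kernel_region(config: LocalConfig) -> KernelRegion:
    """Kernel of the deformed shell: intersection of its face half-spaces.

    Each oriented triangle (outward in the reference shell) contributes the
    half-space on its inner side; feasibility and the Chebyshev center are
    computed by LP.  A non-empty kernel certifies (star-shape argument)
    that placing the center voxel at the returned point yields a locally
    fold-free configuration.
    """
    P = config.neighbor_positions
    p0 = P[config.faces[:, 0]]
    n = np.cross(P[config.faces[:, 1]] - p0, P[config.faces[:, 2]] - p0)
    b = np.einsum("ij,ij->i", n, p0)
    lo = P.min(axis=0) - 2.0
    hi = P.max(axis=0) + 2.0
    return _chebyshev_lp(n, b, lo, hi)


def kernel_region_2d(vertices: np.ndarray) -> KernelRegion:
    """Kernel of a simple 2D polygon (companion routine / test oracle hook).

    Half-planes are taken on the interior side of each edge (orientation
    fixed from the polygon's signed area); returns the Chebyshev center.
    """
    V = np.asarray(vertices, dtype=float)
    nv = len(V)
    area2 = sum(
        V[i, 0] * V[(i + 1) % nv, 1] - V[(i + 1) % nv, 0] * V[i, 1] for i in range(nv)
    )
    orient = 1.0 if area2 > 0 else -1.0
    normals, offs = [], []
    for i in range(nv):
        e = V[(i + 1) % nv] - V[i]
        # interior of a CCW polygon lies left of each edge
        n = orient * np.array([e[1], -e[0]])
        normals.append(n)
        offs.append(np.dot(n, V[i]))
    lo = V.min(axis=0) - 1.0
    hi = V.max(axis=0) + 1.0
    return _chebyshev_lp(np.array(normals), np.array(offs), lo, hi)


def correct_voxel(phi: DisplacementField, x, kern: KernelRegion) -> DisplacementField:
    """Move the deformed position of voxel x to the kernel's interior point."""
    if not kern.nonempty:
        raise EmptyKernelError("cannot correct with an empty kernel")
    out = phi.copy()
    x = tuple(int(v) for v in x)
    out.d[:, x[0], x[1], x[2]] = kern.point - np.array(x, dtype=float)
    return out


def _neighbor_centroid(phi: DisplacementField, y) -> np.ndarray:
    """Centroid of the deformed positions of y's in-bounds 26 neighbors."""
    shape = phi.grid.shape
    pts = []
    base = np.array(y, dtype=float)
    for off in SHELL_OFFSETS:
        q = base + off
        qi = tuple(int(v) for v in q)
        if all(0 <= c < s for c, s in zip(qi, shape)):
            pts.append(q + phi.d[:, qi[0], qi[1], qi[2]])
    return np.mean(pts, axis=0)


def most_concave_neighbor(config: LocalConfig) -> tuple:
    """Neighbor offset whose deformed position deviates most from the
    best-fit affine map of the 26-neighbor shell (the operational reading
    of 'coordinate variance')."""
    O = np.hstack([SHELL_OFFSETS, np.ones((26, 1))])
    B, *_ = np.linalg.lstsq(O, config.neighbor_positions, rcond=None)
    residuals = np.linalg.norm(config.neighbor_positions - O @ B, axis=1)
    return tuple(int(v) for v in SHELL_OFFSETS[int(np.argmax(residuals))])


def _adjust_neighbor_inplace(phi: DisplacementField, x, eta: float) -> tuple | None:
    """In-place core of :func:`adjust_neighbor`; returns the shifted voxel."""
    if eta == 0:
        return None
    config = local_configuration(phi, x)
    off = most_concave_neighbor(config)
    y = tuple(int(a + b) for a, b in zip(x, off))
    target = None
    shape = phi.grid.shape
    if all(1 <= c < s - 1 for c, s in zip(y, shape)):
        kern_y = kernel_region(local_configuration(phi, y))
        if kern_y.nonempty:
            target = kern_y.point
    if target is None:
        target = _neighbor_centroid(phi, y)
    pos = np.array(y, dtype=float) + phi.d[:, y[0], y[1], y[2]]
    new_pos = pos + eta * (target - pos)
    phi.d[:, y[0], y[1], y[2]] = new_pos - np.array(y, dtype=float)
    return y


def adjust_neighbor(phi: DisplacementField, x, eta: float) -> DisplacementField:
    """Shift the most concave neighbor of x toward its own local kernel.

    Used when the kernel at x is empty: the offending neighbor (largest
    affine-fit residual) is moved fraction ``eta`` toward the Chebyshev
    center of its own shell kernel, or toward its local neighbor centroid
    when that kernel is empty or the neighbor sits on the boundary.
    """
    out = phi.copy()
    _adjust_neighbor_inplace(out, x, eta)
    return out


# ---------------------------------------------------------------------------
# Full correction procedure
# ---------------------------------------------------------------------------

def _blend_weight(mask: np.ndarray, radius: int) -> np.ndarray:
    """Ramped blending weight around the folding set.

    1 on the folding voxels, linearly decaying to 0 at Chebyshev distance
    ``radius + 1``, so the fused field only replaces the input locally.
    """
    if not mask.any():
        return np.zeros(mask.shape)
    D = ndimage.distance_transform_cdt(~mask, metric="chessboard").astype(float)
    return np.clip((radius + 1.0 - D) / (radius + 1.0), 0.0, 1.0)


def mfdc_correct(phi: DisplacementField, cfg: MFDCConfig | None = None):
    """Run the full MFDC procedure on a displacement field.

    Returns ``(corrected_field, FoldingReport)``.  A fold-free input is
    returned unchanged.  Otherwise fusion and geometric repair alternate;
    if the folding count stalls above zero the fusion is re-run with a
    halved density threshold (up to ``R_max`` rounds).  The report's
    ``converged`` flag is the authoritative statement: the routine never
    silently returns a folded field.
    """
    cfg = cfg or MFDCConfig()
    fm0 = folding_set(phi)
    report = FoldingReport(mfn_initial=fm0.count, mfn_final=fm0.count)
    report.mfn_history.append(fm0.count)
    if fm0.count == 0:
        report.converged = True
        return phi.copy(), report

    current = phi.copy()
    tau = cfg.tau
    interior_lo = 1
    for outer in range(1, cfg.R_max + 1):
        report.outer_rounds = outer
        # --- folding-aware fusion, blended locally around the folding set
        fm = folding_set(current)
        if fm.count > 0:
            J = jacobian_determinant(current)
            rho = folding_density(fm, cfg.sigma_rho)
            round_cfg = MFDCConfig(
                k=cfg.k, tau=tau, eps=cfg.eps, beta=cfg.beta,
                sigma_rho=cfg.sigma_rho, T_max=cfg.T_max, R_max=cfg.R_max,
                eta=cfg.eta, w_folding=cfg.w_folding,
            )
            weights = fusion_weights(rho, J, round_cfg)
            fused = fuse(build_pyramid(current), weights)
            w = _blend_weight(fm.mask, radius=outer)
            current = DisplacementField(
                current.grid, current.d + w[None] * (fused.d - current.d)
            )
        # --- geometric kernel-repair loop
        prev_count = None
        for _ in range(cfg.T_max):
            fm_s = folding_set(current)
            report.mfn_history.append(fm_s.count)
            if fm_s.count == 0:
                break
            if prev_count is not None and fm_s.count >= prev_count:
                break  # stalled: fall back to stronger coarse mixing
            prev_count = fm_s.count
            report.inner_iterations += 1
            shape = current.grid.shape
            for x in zip(*np.nonzero(fm_s.mask)):
                if any(c < interior_lo or c >= s - 1 for c, s in zip(x, shape)):
                    continue  # boundary folds are fusion's job
                x = tuple(int(c) for c in x)
                kern = kernel_region(local_configuration(current, x))
                if kern.nonempty:
                    current.d[:, x[0], x[1], x[2]] = kern.point - np.array(x, float)
                    report.corrected_voxels.append(x)
                else:
                    moved = _adjust_neighbor_inplace(current, x, cfg.eta)
                    if moved is not None:
                        report.corrected_voxels.append(moved)
        final = folding_set(current)
        report.mfn_final = final.count
        if final.count == 0:
            report.converged = True
            break
        tau = tau / 2.0  # outer fallback: push weight toward coarse levels
    return current, report
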