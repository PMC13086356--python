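"""Loss terms and registration-quality metrics.

The loss suite mirrors the variational objective of the symmetric
multiscale framework: a windowed NCC similarity over scales (coarse fields
upsampled to full resolution before warping), a ReLU Jacobian penalty, an
L2 smoothness penalty on displacement gradients, a cycle-consistency term
on composed forward/backward fields, and the control-increment constraint
residual.  These are evaluation-grade numerical implementations (no
autograd).

Quality metrics: per-label Dice, (percentile) Hausdorff distance in
physical units, volume-wise SSIM, and MFN — the count of voxels with
non-positive Jacobian determinant.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.metrics import structural_similarity

from .correction import folding_set
from .fields import (
    DisplacementField,
    GridMismatchError,
    ScalarMap,
    compose,
    displacement_jacobian,
    jacobian_determinant,
    resample,
    warp_volume,
)
from .homotopy import cic_residual

NCC_EPS = 1e-5


@dataclass
class LossWeights:
    """Weights of the total objective; defaults follow the reference setup
    (lambda1 = 0.8 applied uniformly across scales, lambda2 = 1e-4,
    lambda3 = 1, lambda4 = 0.1, lambda5 = 0.1)."""

    lambda1: tuple = (0.8, 0.8, 0.8, 0.8, 0.8)
    lambda2: float = 1e-4
    lambda3: float = 1.0
    lambda4: float = 0.1
    lambda5: float = 0.1

    def __post_init__(self):
        lam1 = tuple(float(v) for v in np.atleast_1d(self.lambda1))
        if any(v < 0 for v in lam1) or min(self.lambda2, self.lambda3, self.lambda4, self.lambda5) < 0:
            raise ValueError("loss weights must be nonnegative")
        self.lambda1 = lam1


@dataclass
class MultiscaleSolution:
    """Per-scale forward/backward fields (ell = 1 coarsest .. L finest).

    ``fwd[ell]``/``bwd[ell]`` live on the scale-ell grid (full grid divided
    by 2^(L-ell)).  ``cic_terms`` optionally stores, per scale and
    direction, a list of (u, h_prev, h_next, dt) tuples for the
    control-increment constraint loss.
    """

    fwd: list
    bwd: list
    cic_terms: list = dc_field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.fwd)


def _upsample_to(field: DisplacementField, target_shape) -> DisplacementField:
    out = field
    while tuple(out.grid.shape) != tuple(target_shape):
        out = resample(out, 2.0, anti_alias=False)
        if any(a > b for a, b in zip(out.grid.shape, target_shape)):
            raise GridMismatchError(
                f"scale grid {field.grid.shape} does not chain to {target_shape}"
            )
    return out


def ncc(a: ScalarMap, b: ScalarMap, window: int = 9) -> float:
    """Mean local windowed normalized cross-correlation, in [-1, 1].

    Constant-within-window regions have zero covariance and contribute 0.
    """
    if a.grid.shape != b.grid.shape:
        raise GridMismatchError("NCC operands on different grids")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    x, y = a.values, b.values

    def box(v):
        return ndimage.uniform_filter(v, size=window, mode="reflect")

    mx, my = box(x), box(y)
    cross = box(x * y) - mx * my
    var_x = np.maximum(box(x * x) - mx * mx, 0.0)
    var_y = np.maximum(box(y * y) - my * my, 0.0)
    cc = cross / np.sqrt((var_x + NCC_EPS) * (var_y + NCC_EPS))
    return float(np.clip(cc, -1.0, 1.0).mean())


def similarity_loss(
    X: ScalarMap, Y: ScalarMap, solution: MultiscaleSolution, w: LossWeights, window: int = 9
) -> float:
    """L_sim = -sum_ell lambda1_ell [NCC(X∘P(phi_ell), Y) + NCC(X, Y∘P(phi_ell^-1))]

    where P upsamples coarse fields to the full grid (chained trilinear
    doubling) before warping.
    """
    lam = w.lambda1
    if len(lam) == 1:
        lam = lam * solution.L
    if len(lam) < solution.L:
        raise ValueError("need one lambda1 per scale")
    total = 0.0
    for ell in range(solution.L):
        phi = _upsample_to(solution.fwd[ell], X.grid.shape)
        phi_inv = _upsample_to(solution.bwd[ell], X.grid.shape)
        term = ncc(warp_volume(X, phi), Y, window) + ncc(X, warp_volume(Y, phi_inv), window)
        total -= lam[ell] * term
    return float(total)


def jacobian_loss(solution: MultiscaleSolution) -> float:
    """Sum over scales and voxels of ReLU(-J) for both field directions."""
    total = 0.0
    for phi, phi_inv in zip(solution.fwd, solution.bwd):
        for f in (phi, phi_inv):
            J = jacobian_determinant(f).values
            total += float(np.maximum(-J, 0.0).sum())
    return total


def smooth_loss(solution: MultiscaleSolution) -> float:
    """Sum of squared displacement-gradient norms over scales and directions.

    Gradients are taken of the displacement (the identity costs zero), with
    the shared finite-difference stencils.
    """
    total = 0.0
    for phi, phi_inv in zip(solution.fwd, solution.bwd):
        for f in (phi, phi_inv):
            g = displacement_jacobian(f.d)
            total += float((g ** 2).sum())
    return total


def cycle_loss(
    X: ScalarMap, Y: ScalarMap, phi: DisplacementField, phi_inv: DisplacementField, window: int = 9
) -> float:
    """L_cycle = -NCC(X, X∘(phi∘phi^-1)) - NCC(Y, Y∘(phi^-1∘phi))."""
    fwd_cycle = compose(phi, phi_inv)
    bwd_cycle = compose(phi_inv, phi)
    return float(
        -ncc(X, warp_volume(X, fwd_cycle), window) - ncc(Y, warp_volume(Y, bwd_cycle), window)
    )


def cic_loss(solution: MultiscaleSolution) -> float:
    """Summed control-increment constraint residual over scales, directions
    and time steps; vanishes when every h was evolved by the divergence
    constraint."""
    total = 0.0
    for scale_terms in solution.cic_terms:
        for direction_terms in scale_terms:
            for (u, h_prev, h_next, dt) in direction_terms:
                total += float(cic_residual(u, h_prev, h_next, dt).values.sum())
    return total


def total_loss(
    X: ScalarMap,
    Y: ScalarMap,
    solution: MultiscaleSolution,
    w: LossWeights | None = None,
    window: int = 9,
) -> dict:
    """Weighted total objective; returns the components and their sum."""
    w = w or LossWeights()
    phi_full = _upsample_to(solution.fwd[-1], X.grid.shape)
    phi_inv_full = _upsample_to(solution.bwd[-1], X.grid.shape)
    parts = {
        "similarity": similarity_loss(X, Y, solution, w, window),
        "jacobian": jacobian_loss(solution),
        "smooth": smooth_loss(solution),
        "cycle": cycle_loss(X, Y, phi_full, phi_inv_full, window),
        "cic": cic_loss(solution),
    }
    parts["total"] = (
        parts["similarity"]
        + w.lambda2 * parts["jacobian"]
        + w.lambda3 * parts["smooth"]
        + w.lambda4 * parts["cycle"]
        + w.lambda5 * parts["cic"]
    )
    return parts


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------

def dsc(labels_a: ScalarMap, labels_b: ScalarMap) -> dict:
    """Per-label Dice 2|A∩B| / (|A|+|B|) plus the mean over labels present
    in at least one volume (background label 0 excluded)."""
    if labels_a.grid.shape != labels_b.grid.shape:
        raise GridMismatchError("label volumes on different grids")
    a = labels_a.values.astype(int)
    b = labels_b.values.astype(int)
    labels = sorted(set(np.unique(a)) | set(np.unique(b)) - {0})
    labels = [l for l in labels if l != 0]
    per_label = {}
    for lab in labels:
        ma, mb = a == lab, b == lab
        denom = ma.sum() + mb.sum()
        per_label[int(lab)] = float(2.0 * np.logical_and(ma, mb).sum() / denom) if denom else np.nan
    valid = [v for v in per_label.values() if not np.isnan(v)]
    return {"per_label": per_label, "mean": float(np.mean(valid)) if valid else np.nan}


def _surface_points(mask: np.ndarray, spacing) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    surf = mask & ~eroded
    pts = np.argwhere(surf).astype(float)
    return pts * np.asarray(spacing)[None, :]


def hausdorff(mask_a: ScalarMap, mask_b: ScalarMap, percentile: float | None = None) -> float:
    """Symmetric (percentile) Hausdorff distance between mask surfaces, in
    physical units from the grid spacing."""
    if mask_a.grid.shape != mask_b.grid.shape:
        raise GridMismatchError("masks on different grids")
    sa = _surface_points(mask_a.values > 0, mask_a.grid.spacing)
    sb = _surface_points(mask_b.values > 0, mask_b.grid.spacing)
    if len(sa) == 0 or len(sb) == 0:
        return np.nan
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def ssim(a: ScalarMap, b: ScalarMap, window: int = 7) -> float:
    """Volume-wise mean structural similarity (standard constants)."""
    if a.grid.shape != b.grid.shape:
        raise GridMismatchError("SSIM operands on different grids")
    both = np.concatenate([a.values.ravel(), b.values.ravel()])
    data_range = float(both.max() - both.min())
    if data_range == 0:
        return 1.0
    return float(
        structural_similarity(a.values, b.values, win_size=window, data_range=data_range)
    )


def mfn(phi: DisplacementField) -> int:
    """Number of voxels with non-positive Jacobian determinant."""
    return folding_set(phi, inclusive=True).count
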