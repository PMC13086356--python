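"""Non-learned multiscale symmetric registration driver.

A desk-scale instantiation of the cascade contract: Gaussian intensity
pyramids stand in for learned feature pyramids and a demons-type force
stands in for the learned increment predictor, while the actual deformation
updates go through the homotopy control-increment integrator.  The cascade
runs coarse to fine over L scales with N control-increment steps per scale,
initializing each scale from the x2-upsampled previous-scale field, and
estimating forward and backward increments with the same provider on
swapped image pairs (the shared-weight analogue).  The multiscale
folding-aware correction is applied to both outputs by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correction import MFDCConfig, mfdc_correct
from .fields import (
    DisplacementField,
    Grid,
    GridMismatchError,
    ScalarMap,
    gaussian_smooth,
    identity_field,
    resample_to_shape,
    warp_volume,
)
from .homotopy import (
    ControlIncrement,
    IntegrationState,
    Schedule,
    initial_homotopy,
    integrate,
)
from .metrics import mfn, ncc


@dataclass
class RegConfig:
    """Registration settings.

    L : number of spatial scales (coarse to fine).
    N : control-increment cascades (time steps) per scale.
    sigma_force : Gaussian smoothing of the demons force, voxels.
    step_scale : per-step increment magnitude cap, voxels.
    sigma_h : bandwidth of the homotopy evaluation, voxels.
    run_mfdc : apply the folding-aware correction to the outputs.
    """

    L: int = 5
    N: int = 4
    sigma_force: float = 2.0
    step_scale: float = 1.0
    sigma_h: float = 2.0
    run_mfdc: bool = True
    mfdc: MFDCConfig | None = None
    ncc_window: int = 9

    def __post_init__(self):
        if self.L < 1 or self.N < 1:
            raise ValueError("need L >= 1 and N >= 1")
        if self.sigma_force <= 0 or self.step_scale <= 0 or self.sigma_h <= 0:
            raise ValueError("smoothing and cap parameters must be positive")


def increment_provider(
    warped_moving: ScalarMap, fixed: ScalarMap, cfg: RegConfig
) -> ControlIncrement:
    """Demons-type control increment from an image pair.

    f = (Y - Xw) * grad(Xw) / (|grad(Xw)|^2 + (Y - Xw)^2 + delta),

    Gaussian-smoothed (sigma_force) and zeroed on the boundary shell (the
    control boundary condition).  The increment is the force scaled by the
    number of cascade steps, u = N * f, so that integrating u against the
    step length 1/N applies one demons step per cascade stage; the
    resulting per-step displacement dt * u is capped at ``step_scale``
    voxels per step.
    """
    if warped_moving.grid.shape != fixed.grid.shape:
        raise GridMismatchError("images on different grids")
    Xw, Y = warped_moving.values, fixed.values
    diff = Y - Xw
    g = np.stack([np.gradient(Xw, axis=ax, edge_order=1) for ax in range(3)])
    denom = (g ** 2).sum(axis=0) + diff ** 2 + 1e-9
    u = diff[None] * g / denom
    u = gaussian_smooth(u, cfg.sigma_force)
    u = cfg.N * u
    norms = np.linalg.norm(u, axis=0)
    cap = cfg.step_scale * cfg.N  # dt * |u| <= step_scale
    over = norms > cap
    if np.any(over):
        scale = np.ones_like(norms)
        scale[over] = cap / norms[over]
        u = u * scale[None]
    boundary = ~warped_moving.grid.interior
    u[:, boundary] = 0.0
    return ControlIncrement(warped_moving.grid, u)


def _pyramid_shapes(shape, L):
    """Coarse-to-fine shape chain; truncates L where an axis would drop below 3."""
    shapes = [tuple(shape)]
    while len(shapes) < L:
        nxt = tuple(int(round(n / 2)) for n in shapes[-1])
        if any(n < 3 for n in nxt):
            break
        shapes.append(nxt)
    return list(reversed(shapes))  # coarsest first


def register(X: ScalarMap, Y: ScalarMap, cfg: RegConfig | None = None):
    """Symmetric multiscale registration of moving X onto fixed Y.

    Returns ``(phi, phi_inv, report)`` with both fields on the full grid.
    The report carries per-scale NCC, the minimum Jacobian determinant and
    MFN, plus the correction reports when ``run_mfdc`` is on.
    """
    cfg = cfg or RegConfig()
    if X.grid.shape != Y.grid.shape:
        raise GridMismatchError("moving and fixed images on different grids")
    shapes = _pyramid_shapes(X.grid.shape, cfg.L)

    report = {"scales": [], "mfdc": None}
    phi = phi_inv = None
    for level, shape in enumerate(shapes):
        if tuple(shape) == tuple(X.grid.shape):
            Xl, Yl = X, Y
        else:
            # intensity pyramid: anti-aliased downsampling stands in for
            # learned multiscale features
            Xl = resample_to_shape(X, shape, anti_alias=True)
            Yl = resample_to_shape(Y, shape, anti_alias=True)
        grid = Xl.grid
        if phi is None:
            phi, phi_inv = identity_field(grid), identity_field(grid)
        else:
            phi = resample_to_shape(phi, shape, anti_alias=False)
            phi_inv = resample_to_shape(phi_inv, shape, anti_alias=False)

        # h restarts at 1 on each scale; each scale spans its own unit time
        state = IntegrationState(
            grid=grid,
            phi_fwd=phi,
            phi_bwd=phi_inv,
            h_fwd=initial_homotopy(grid),
            h_bwd=initial_homotopy(grid),
        )

        def provider(s):
            u_f = increment_provider(warp_volume(Xl, s.phi_fwd), Yl, cfg)
            u_b = increment_provider(warp_volume(Yl, s.phi_bwd), Xl, cfg)
            return u_f, u_b

        state = integrate(provider, Schedule(cfg.N), grid, sigma=cfg.sigma_h, initial=state)
        phi, phi_inv = state.phi_fwd, state.phi_bwd
        phi_full = (
            phi if tuple(shape) == tuple(X.grid.shape)
            else resample_to_shape(phi, X.grid.shape, anti_alias=False)
        )
        report["scales"].append(
            {
                "shape": list(shape),
                "ncc": ncc(warp_volume(Xl, phi), Yl, cfg.ncc_window),
                "ncc_full": ncc(warp_volume(X, phi_full), Y, cfg.ncc_window),
                "min_J": min(state.min_J_history),
                "mfn": mfn(phi),
            }
        )

    if cfg.run_mfdc:
        phi, rep_f = mfdc_correct(phi, cfg.mfdc)
        phi_inv, rep_b = mfdc_correct(phi_inv, cfg.mfdc)
        report["mfdc"] = {"forward": rep_f.to_dict(), "backward": rep_b.to_dict()}
    report["final_ncc"] = ncc(warp_volume(X, phi), Y, cfg.ncc_window)
    report["final_mfn"] = mfn(phi)
    return phi, phi_inv, report
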