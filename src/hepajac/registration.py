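"""Contour-driven registration: rigid mask alignment and Demons on
signed distance transforms.

Longitudinal liver CTs cannot be registered reliably on intensities
(contrast and disease change between scans), so all registration here is
driven by binary organ masks.  Rigid alignment uses centroids and
principal axes of the mask with overlap-based sign disambiguation.
Deformable alignment uses a symmetric-forces Demons iteration on the
signed distance transforms of the masks -- binary images have zero
gradient almost everywhere, while their distance transforms carry the
surface geometry into the whole volume -- with Gaussian fluid (update)
and diffusion (total field) regularisation and a Dice stopping rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .grids import DisplacementField, Geometry, LabelGrid, RigidTransform

__all__ = ["DemonsParams", "DemonsResult", "rigid_align", "demons_register", "dice"]

logger = logging.getLogger(__name__)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return float(2.0 * np.logical_and(a, b).sum() / denom) if denom else 1.0


def _as_mask(m: LabelGrid | np.ndarray) -> tuple[np.ndarray, Geometry | None]:
    if isinstance(m, LabelGrid):
        return m.labels > 0, m.geometry
    return np.asarray(m, bool), None


def _mask_points_mm(mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    return np.argwhere(mask) * spacing + origin


def rigid_align(fixed_mask: LabelGrid, moving_mask: LabelGrid) -> RigidTransform:
    """Rigid transform taking the moving mask onto the fixed mask.

    Centroid alignment followed by principal-axes (inertia) alignment; the
    four proper-rotation sign combinations are disambiguated by overlap of
    the transformed point cloud with the fixed mask.  Nearly isotropic
    inertia (no reliable axes) falls back to centroid-only with a warning;
    so does any axes choice that fails to improve overlap.
    """
    f, fgeom = _as_mask(fixed_mask)
    m, mgeom = _as_mask(moving_mask)
    if not f.any() or not m.any():
        raise ValueError("rigid_align requires non-empty masks")
    fsp, fo = np.asarray(fgeom.spacing), np.asarray(fgeom.origin)
    msp, mo = np.asarray(mgeom.spacing), np.asarray(mgeom.origin)
    fp = _mask_points_mm(f, fsp, fo)
    mp = _mask_points_mm(m, msp, mo)
    fc, mc = fp.mean(0), mp.mean(0)

    def overlap(transform: RigidTransform) -> float:
        pts = transform.apply(mp)
        idx = np.round((pts - fo) / fsp).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(f.shape)), axis=1)
        return float(f[tuple(idx[ok].T)].sum()) / len(mp)

    centroid_only = RigidTransform(np.eye(3), fc - mc)
    best, best_score = centroid_only, overlap(centroid_only)

    covf = np.cov((fp - fc).T)
    covm = np.cov((mp - mc).T)
    wf, vf = np.linalg.eigh(covf)
    wm, vm = np.linalg.eigh(covm)
    aniso = min(np.ptp(wf) / max(wf.max(), 1e-12), np.ptp(wm) / max(wm.max(), 1e-12))
    if aniso < 0.05:
        logger.warning("rigid_align: nearly spherical inertia; centroid-only alignment")
        return best
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            signs = np.array([s1, s2, s1 * s2])  # keeps det = +1
            r = vf @ np.diag(signs) @ vm.T
            if np.linalg.det(r) < 0:
                r = vf @ np.diag(-signs) @ vm.T
            cand = RigidTransform(r, fc - r @ mc)
            score = overlap(cand)
            if score > best_score:
                best, best_score = cand, score
    return best


@dataclass(frozen=True)
class DemonsParams:
    """Symmetric-forces Demons settings (all lengths in mm)."""

    sigma_fluid_mm: float = 2.0
    sigma_diffusion_mm: float = 2.0
    max_iters: int = 100
    dice_stop: float = 0.98
    step_scale: float = 0.8
    max_step_mm: float = 2.0
    check_every: int = 2


@dataclass
class DemonsResult:
    """Field plus convergence diagnostics; non-convergence is flagged, not silent."""

    field: DisplacementField
    final_dice: float
    iterations: int
    converged: bool


def demons_register(
    fixed_mask: LabelGrid | np.ndarray,
    moving_mask: LabelGrid | np.ndarray,
    params: DemonsParams | None = None,
    geometry: Geometry | None = None,
) -> DemonsResult:
    """Demons on signed distance transforms of two same-geometry masks.

    Returns the field u such that moving(x + u(x)) matches fixed(x); with
    fixed = pre-treatment and moving = post-treatment masks this is the
    forward pre-to-post displacement.  Stops once the Dice overlap of the
    warped moving mask with the fixed mask reaches ``dice_stop``.
    """
    params = params or DemonsParams()
    f, fgeom = _as_mask(fixed_mask)
    m, mgeom = _as_mask(moving_mask)
    geom = fgeom or geometry
    if geom is None:
        raise ValueError("geometry required for bare-array masks")
    if mgeom is not None and mgeom != geom:
        raise ValueError("masks must share one geometry (rigidly pre-align first)")
    if f.shape != m.shape:
        raise ValueError("masks must share one grid")
    sp = np.asarray(geom.spacing, float)

    def sdt(mask: np.ndarray) -> np.ndarray:
        inside = ndi.distance_transform_edt(mask, sampling=sp)
        outside = ndi.distance_transform_edt(~mask, sampling=sp)
        return (outside - inside).astype(np.float32)

    fs, ms = sdt(f), sdt(m)
    grad_f = np.stack(np.gradient(fs, *sp), axis=-1)
    grad_m = np.stack(np.gradient(ms, *sp), axis=-1)

    base = np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.float32) for n in f.shape), indexing="ij"),
        axis=-1,
    )
    u = np.zeros(f.shape + (3,), dtype=np.float32)
    sig_fluid = params.sigma_fluid_mm / sp
    sig_diff = params.sigma_diffusion_mm / sp
    d = dice(f, m)
    it = 0
    for it in range(1, params.max_iters + 1):
        idx = base + u / sp
        coords = [idx[..., ax] for ax in range(3)]
        mw = ndi.map_coordinates(ms, coords, order=1, mode="nearest")
        jw = np.stack(
            [ndi.map_coordinates(grad_m[..., ax], coords, order=1, mode="nearest")
             for ax in range(3)],
            axis=-1,
        )
        j = 0.5 * (grad_f + jw)
        diff = fs - mw
        jj = (j * j).sum(axis=-1)
        # normalization length ~2x the max step keeps steps near max_step_mm
        # for large surface offsets without oscillation near convergence
        denom = jj + (diff / (2.0 * params.max_step_mm)) ** 2
        scale = np.where(denom > 1e-9, diff / np.maximum(denom, 1e-9), 0.0)
        step = params.step_scale * scale[..., None] * j
        norm = np.sqrt((step * step).sum(-1, keepdims=True))
        step *= np.minimum(1.0, params.max_step_mm / np.maximum(norm, 1e-9))
        for ax in range(3):
            step[..., ax] = ndi.gaussian_filter(step[..., ax], sig_fluid)
        u += step
        for ax in range(3):
            u[..., ax] = ndi.gaussian_filter(u[..., ax], sig_diff)
        if it % params.check_every == 0 or it == params.max_iters:
            idx = base + u / sp
            warped = ndi.map_coordinates(
                m.astype(np.float32), [idx[..., ax] for ax in range(3)], order=1, mode="constant"
            ) >= 0.5
            d = dice(f, warped)
            if d >= params.dice_stop:
                break
    converged = d >= params.dice_stop
    if d < 0.90:
        logger.warning("demons did not converge: Dice %.3f after %d iterations", d, it)
    return DemonsResult(
        field=DisplacementField(u.astype(float), geom.spacing, geom.origin),
        final_dice=d,
        iterations=it,
        converged=converged,
    )
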