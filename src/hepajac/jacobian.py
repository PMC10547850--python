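"""Voxel-wise volume-change maps from displacement fields.

The local volume ratio of the mapping x -> x + u(x) is the determinant of
its Jacobian, |J|(x) = det(I + grad u(x)).  Reported with a negative offset
of 1 so that negative values read as local contraction (atrophy) and
positive values as expansion (hypertrophy); deformations outside the liver
are discarded (|J| = 1, i.e. dv = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import DisplacementField, Grid3D, LabelGrid

__all__ = ["VolumeChangeMap", "jacobian_determinant", "volume_change_map"]

logger = logging.getLogger(__name__)


@dataclass
class VolumeChangeMap:
    """|J| - 1 as a dimensionless fraction; exactly 0 outside the liver."""

    dv: Grid3D
    n_folding_voxels: int = 0  # liver voxels where |J| <= 0 (non-physical)

    @property
    def values(self) -> np.ndarray:
        return self.dv.values


def _gradient_axis(comp: np.ndarray, axis: int, spacing: float) -> np.ndarray:
    # central differences interior, one-sided at the faces
    return np.gradient(comp, spacing, axis=axis)


def jacobian_determinant(dvf: DisplacementField) -> Grid3D:
    """det(I + grad u) per voxel.

    Displacement gradients are taken by central differences scaled by the
    voxel spacing (one-sided at the volume faces), which is exact for
    affine fields.
    """
    u = dvf.u
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field contains non-finite values")
    sp = dvf.spacing
    # grad[i][j] = d u_i / d x_j
    g = np.empty(u.shape[:3] + (3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            g[..., i, j] = _gradient_axis(u[..., i], j, sp[j])
    f = g.copy()
    for i in range(3):
        f[..., i, i] += 1.0
    det = (
        f[..., 0, 0] * (f[..., 1, 1] * f[..., 2, 2] - f[..., 1, 2] * f[..., 2, 1])
        - f[..., 0, 1] * (f[..., 1, 0] * f[..., 2, 2] - f[..., 1, 2] * f[..., 2, 0])
        + f[..., 0, 2] * (f[..., 1, 0] * f[..., 2, 1] - f[..., 1, 1] * f[..., 2, 0])
    )
    return Grid3D(det, dvf.spacing, dvf.origin)


def volume_change_map(jac: Grid3D, liver_mask: LabelGrid | np.ndarray) -> VolumeChangeMap:
    """dv = |J| - 1 inside the liver, exactly 0 outside.

    Liver voxels with |J| <= 0 (folding: non-invertible local mapping) are
    counted and reported, never clamped silently.
    """
    mask = liver_mask.liver_mask() if isinstance(liver_mask, LabelGrid) else np.asarray(liver_mask, bool)
    if mask.shape != jac.shape:
        raise ValueError("liver mask shape does not match the Jacobian grid")
    vals = np.asarray(jac.values, dtype=float)
    n_fold = int(np.count_nonzero(vals[mask] <= 0))
    if n_fold:
        logger.warning("volume_change_map: %d folding voxels (|J| <= 0) inside liver", n_fold)
    dv = np.zeros_like(vals)
    dv[mask] = vals[mask] - 1.0
    return VolumeChangeMap(Grid3D(dv, jac.spacing, jac.origin), n_folding_voxels=n_fold)
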