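"""Volume data model and NIfTI I/O.

All volumes in the pipeline -- CT (HU), dose (Gy), EQD2 (Gy), volume-change
maps (dimensionless fraction), label maps -- live on axis-aligned 3D lattices.
Axis order is left-right / anterior-posterior / superior-inferior; voxel
indices are 0-based and the world coordinate (mm) of index ``i`` is
``origin + i * spacing``.  Oblique orientations are not supported: phantom
volumes are axis-aligned by construction and the rigid dose-mapping
approximation keeps them so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "Geometry",
    "Grid3D",
    "LabelGrid",
    "DisplacementField",
    "RigidTransform",
    "Box",
    "read_volume",
    "write_volume",
    "read_dvf",
    "write_dvf",
    "resample_to",
    "crop_box_with_margins",
    "box_geometry",
    "apply_rigid",
]


@dataclass(frozen=True)
class Geometry:
    """Lattice geometry: shape (voxels), spacing (mm/voxel) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive and finite, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of (possibly fractional) voxel indices."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def index(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world coordinates (mm)."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse open meshgrid of integer voxel indices."""
        return np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij", sparse=True)

    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a


@dataclass
class Grid3D:
    """A scalar lattice with geometry.  Units depend on role (HU, Gy, fraction)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Grid3D requires a 3D array, got ndim={self.values.ndim}")
        # validates spacing/shape
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        Geometry(self.values.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.shape, self.spacing, self.origin)

    def like(self, values: np.ndarray) -> "Grid3D":
        """New Grid3D with the same geometry and the given values."""
        if tuple(values.shape) != self.shape:
            raise ValueError("values shape does not match grid shape")
        return Grid3D(values, self.spacing, self.origin)


@dataclass
class LabelGrid:
    """Integer label lattice on a Grid3D geometry.

    Segment convention: 0 = background, 1-4 = Couinaud-like segments
    (1 caudate, 2-4 left-lobe segments), 5 = right lobe (segments 5-8
    merged).  The liver is the union of labels 1-5.  A vessel mask, where
    present, travels as a separate boolean lattice so the segment labels
    partition the liver exactly.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: Mapping[int, str] = field(
        default_factory=lambda: {
            0: "background",
            1: "seg1",
            2: "seg2",
            3: "seg3",
            4: "seg4",
            5: "right_lobe",
        }
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelGrid requires a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelGrid requires integer labels")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        Geometry(self.labels.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.shape, self.spacing, self.origin)

    def liver_mask(self) -> np.ndarray:
        """Boolean liver mask: union of labels 1-5."""
        return (self.labels >= 1) & (self.labels <= 5)

    def region_mask(self, region: str) -> np.ndarray:
        """Mask for one analysis region.

        Regions: ``whole_liver``, ``seg1``..``seg4``, ``right_lobe``
        (label 5) and ``left_lobe`` (union of segments 2-4).
        """
        lab = self.labels
        if region == "whole_liver":
            return self.liver_mask()
        if region == "left_lobe":
            return (lab >= 2) & (lab <= 4)
        if region == "right_lobe":
            return lab == 5
        if region.startswith("seg"):
            k = int(region[3:])
            if not 1 <= k <= 4:
                raise KeyError(region)
            return lab == k
        raise KeyError(f"unknown region {region!r}")


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement in mm on a Grid3D geometry.

    Maps a pre-treatment world point ``x`` to its post-treatment position
    ``x + u(x)``; with this convention a Jacobian determinant below one
    reads as local contraction (atrophy).
    """

    u: np.ndarray  # (nx, ny, nz, 3), mm
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("DisplacementField requires a (nx,ny,nz,3) array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        Geometry(self.u.shape[:3], self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.u.shape[:3])

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.shape, self.spacing, self.origin)

    def component(self, axis: int) -> Grid3D:
        return Grid3D(self.u[..., axis], self.spacing, self.origin)


@dataclass
class RigidTransform:
    """World-coordinate rigid map ``x -> R x + t`` (rotation in SO(3), t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length 3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthonormal (det = 1)")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of world points."""
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class Box:
    """Half-open index box ``[lo, hi)`` within a parent geometry."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    parent: Geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def geometry(self) -> Geometry:
        """Geometry of the sub-box at the parent's spacing."""
        return Geometry(self.shape, self.parent.spacing, tuple(self.parent.world(np.asarray(self.lo))))


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_volume(vol: Grid3D | LabelGrid, path: str | Path) -> None:
    """Write a scalar or label volume as NIfTI-1 (.nii / .nii.gz).

    Labels are stored as int16 so that :func:`read_volume` round-trips them
    back into a :class:`LabelGrid`.
    """
    if isinstance(vol, LabelGrid):
        data = vol.labels.astype(np.int16)
    else:
        # stored at native float64 precision so round trips are bit exact
        data = np.asarray(vol.values, dtype=np.float64)
    img = nib.Nifti1Image(data, vol.geometry.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> Grid3D | LabelGrid:
    """Read a NIfTI-1 volume; integer dtype on disk yields a LabelGrid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-finite or non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    if np.issubdtype(data.dtype, np.integer):
        return LabelGrid(data.astype(np.int32), tuple(float(z) for z in zooms), origin)
    return Grid3D(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin)


def write_dvf(dvf: DisplacementField, path: str | Path) -> None:
    """Write a displacement field as 4D NIfTI (last axis = 3 components, mm)."""
    img = nib.Nifti1Image(dvf.u.astype(np.float32), dvf.geometry.affine())
    nib.save(img, str(path))


def read_dvf(path: str | Path) -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such displacement field: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (nx,ny,nz,3) field, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return DisplacementField(np.asarray(data, dtype=float), tuple(float(z) for z in zooms), origin)


# ---------------------------------------------------------------------------
# Resampling


def _sample_at_indices(
    values: np.ndarray, idx: list[np.ndarray], interp: str, fill: float
) -> np.ndarray:
    order = {"linear": 1, "nearest": 0}[interp]
    return ndi.map_coordinates(values, idx, order=order, mode="constant", cval=fill)


def _ref_index_coords(src: Geometry, ref: Geometry) -> list[np.ndarray]:
    """Fractional src indices of every ref voxel center (broadcastable)."""
    coords = []
    for ax in range(3):
        i = np.arange(ref.shape[ax], dtype=float)
        w = ref.origin[ax] + i * ref.spacing[ax]
        shape = [1, 1, 1]
        shape[ax] = ref.shape[ax]
        coords.append(((w - src.origin[ax]) / src.spacing[ax]).reshape(shape))
    return list(np.broadcast_arrays(*coords))


def resample_to(
    vol: Grid3D | LabelGrid,
    ref: Geometry,
    interp: str = "linear",
    fill: float = 0.0,
) -> Grid3D | LabelGrid:
    """Resample a volume onto a reference geometry in world coordinates.

    Linear interpolation for scalars, nearest for labels (required --
    linear interpolation would invent labels).  Out-of-support voxels take
    ``fill`` (default 0: no dose / no change / background).
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    if isinstance(vol, LabelGrid) and interp != "nearest":
        raise ValueError("LabelGrid resampling requires interp='nearest'")
    idx = _ref_index_coords(vol.geometry, ref)
    if isinstance(vol, LabelGrid):
        out = _sample_at_indices(vol.labels, idx, "nearest", fill).astype(vol.labels.dtype)
        return LabelGrid(out, ref.spacing, ref.origin, legend=vol.legend)
    out = _sample_at_indices(np.asarray(vol.values, dtype=float), idx, interp, fill)
    return Grid3D(out, ref.spacing, ref.origin)


def crop_box_with_margins(mask: LabelGrid, margins_vox: tuple[int, int, int]) -> Box:
    """Tight bounding box of the nonzero mask, expanded by per-axis voxel
    margins and clamped to the volume bounds."""
    nz = np.nonzero(mask.labels)
    if nz[0].size == 0:
        raise ValueError("crop_box_with_margins: mask is empty")
    lo, hi = [], []
    for ax in range(3):
        lo.append(max(0, int(nz[ax].min()) - int(margins_vox[ax])))
        hi.append(min(mask.shape[ax], int(nz[ax].max()) + int(margins_vox[ax]) + 1))
    return Box(tuple(lo), tuple(hi), mask.geometry)


def box_geometry(box: Box, grid_shape: tuple[int, int, int]) -> Geometry:
    """Geometry spanning a box's world extent with ``grid_shape`` voxels.

    Voxel centers are spread so the first/last centers coincide with the
    box's first/last voxel centers (endpoint-matched resampling).
    """
    src = box.geometry
    spacing, origin = [], []
    for ax in range(3):
        n_src, n_dst = src.shape[ax], int(grid_shape[ax])
        extent = (n_src - 1) * src.spacing[ax]
        sp = extent / (n_dst - 1) if n_dst > 1 else max(extent, src.spacing[ax])
        spacing.append(sp if sp > 0 else src.spacing[ax])
        origin.append(src.origin[ax])
    return Geometry(tuple(grid_shape), tuple(spacing), tuple(origin))


def apply_rigid(
    vol: Grid3D | LabelGrid,
    transform: RigidTransform,
    ref: Geometry,
    interp: str = "linear",
    fill: float = 0.0,
) -> Grid3D | LabelGrid:
    """Resample a volume through a rigid transform onto ``ref``.

    The output voxel at world point x takes the input value at T^{-1}(x),
    i.e. the volume is moved *forward* by T.
    """
    if isinstance(vol, LabelGrid) and interp != "nearest":
        raise ValueError("LabelGrid resampling requires interp='nearest'")
    inv = transform.inverse()
    ii, jj, kk = np.meshgrid(*(np.arange(n, dtype=float) for n in ref.shape), indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1) * np.asarray(ref.spacing) + np.asarray(ref.origin)
    src_pts = inv.apply(pts.reshape(-1, 3))
    src_geom = vol.geometry
    idx = [
        (src_pts[:, ax] - src_geom.origin[ax]) / src_geom.spacing[ax] for ax in range(3)
    ]
    if isinstance(vol, LabelGrid):
        out = _sample_at_indices(vol.labels, idx, "nearest", fill)
        return LabelGrid(
            out.reshape(ref.shape).astype(vol.labels.dtype), ref.spacing, ref.origin, legend=vol.legend
        )
    out = _sample_at_indices(np.asarray(vol.values, dtype=float), idx, interp, fill)
    return Grid3D(out.reshape(ref.shape), ref.spacing, ref.origin)
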