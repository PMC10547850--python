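"""Synthetic liver-phantom cohort generator.

Emulates the data the analysis pipeline consumes when applied to a real
radiotherapy cohort: for each phantom patient a pre-treatment CT (HU) with
a smooth liver blob partitioned into Couinaud-like regions (caudate-like
segment 1, left-lobe segments 2-4, merged right lobe = label 5) and a
recursive vessel tree; an IMRT-like planned dose focused in one region with
Gaussian falloff and a low-dose beam corridor; and a *planted* spatial
dose -> volume-change response with a known ground-truth deformation.

The planted voxel response is

    g(x) = clip( s_i * [ -atrophy(x) + hyper(x) + remodel(x) ]
                 * (T/147)^tc  +  eps(x),  -0.6, +0.4 )

where atrophy is a saturating function of EQD2 modulated by vascular
sparing and subcapsular vulnerability, hyper is a compensatory term gated
to low dose and proportional to the atrophied liver fraction A, remodel is
a small dose-independent perivascular/subcapsular pattern, s_i is a
per-case log-normal sensitivity, (T/147)^tc a time-gap modulation and eps
smooth spatial noise (see :class:`ResponseParams`).  The anatomy-coupled
terms make the response predictable from pre-treatment images but not
linear in dose -- the premise of the prediction study.  A
displacement field whose Jacobian determinant matches 1+g is constructed
from a curl-free potential (Poisson solve of div u = log(1+g) with a
zero-displacement far boundary) and the post-treatment images and masks are
the forward warp of the pre-treatment ones under that field -- so the
registration pipeline can be scored against known truth.

Cohort-level plan metadata (cancer-type mix 25/64/11 HCC/CC/CRC,
prescriptions 50-100 Gy in 10-28 fractions from the study's empirical
distribution, follow-up gap ~147 +/- 36 d truncated to [79, 257] d) matches
the cohort the pipeline is designed for.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as sfft
from scipy import ndimage as ndi

from .eqd2 import FractionationScheme, eqd2_map
from .grids import (
    DisplacementField,
    Geometry,
    Grid3D,
    LabelGrid,
    read_dvf,
    read_volume,
    write_dvf,
    write_volume,
)

__all__ = [
    "ResponseParams",
    "CohortConfig",
    "SyntheticCase",
    "generate_anatomy",
    "generate_plan",
    "generate_response",
    "plant_response",
    "generate_cohort",
    "write_case",
    "load_case",
    "invert_dvf",
    "warp_volume",
]

logger = logging.getLogger(__name__)

# Empirical plan-metadata distributions of the target cohort.
PRESCRIPTIONS_GY = (50, 52, 52.5, 60, 62.5, 65, 67.5, 69, 70, 75, 100)
PRESCRIPTION_COUNTS = (6, 1, 3, 33, 1, 2, 31, 1, 9, 10, 3)
FRACTION_NUMBERS = (10, 13, 15, 23, 25, 28)
FRACTION_COUNTS = (12, 1, 67, 1, 18, 1)
CANCER_TYPES = ("HCC", "CC", "CRC")
CANCER_PROBS = (0.25, 0.64, 0.11)
T_MEAN_DAYS, T_SD_DAYS, T_RANGE_DAYS = 147.0, 36.0, (79.0, 257.0)


@dataclass(frozen=True)
class ResponseParams:
    """Parameters of the planted dose -> volume-change response.

    slope_per_gy: fractional volume loss per Gy EQD2 (0.0015 puts a
    200 Gy-EQD2 hotspot at -30 %).  dose_threshold_gy: below this the
    compensatory hypertrophy gate opens (smooth logistic of width
    threshold_width_gy).  compensation_gain couples hypertrophy amplitude
    to the atrophied liver fraction A.  patient_sd is the log-normal sigma
    of the per-case sensitivity; voxel_noise_sd the standard deviation of
    smooth within-liver noise; time_coupling the exponent on T/147.

    Two features make the planted response a function of the pre-treatment
    anatomy and not merely of dose: ``max_atrophy`` saturates the
    dose-response (volume loss flattens toward this fraction instead of
    growing linearly forever; ``inf`` recovers the plain linear slope),
    and ``vessel_sparing`` attenuates atrophy near the vessel tree (well
    perfused tissue resists volume loss; 0 disables it).  Both are
    invisible to a linear dose baseline but learnable from the CT channel,
    which is what gives an image-based predictor headroom over the raw
    dose distribution.
    """

    slope_per_gy: float = 0.005
    dose_threshold_gy: float = 50.0
    threshold_width_gy: float = 3.0
    compensation_gain: float = 0.15
    patient_sd: float = 0.3
    voxel_noise_sd: float = 0.06
    time_coupling: float = 0.5
    max_atrophy: float = 0.45
    vessel_sparing: float = 0.5
    vessel_sparing_radius_mm: float = 15.0
    vascular_hypertrophy: float = 1.2
    capsule_enhancement: float = 0.6
    capsule_depth_mm: float = 12.0
    baseline_remodeling: float = 0.08
    construction_smoothing_vox: float = 0.9
    clip_lo: float = -0.6
    clip_hi: float = 0.4

    def __post_init__(self) -> None:
        if self.voxel_noise_sd < 0:
            raise ValueError("voxel_noise_sd must be >= 0")
        for name in ("slope_per_gy", "dose_threshold_gy", "compensation_gain",
                     "patient_sd", "time_coupling"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generation settings: grid, response params, EQD2 mode."""

    shape: tuple[int, int, int] = (64, 64, 40)
    spacing: tuple[float, float, float] = (3.0, 3.0, 4.0)
    response: ResponseParams = field(default_factory=ResponseParams)
    eqd2_mode: str = "as_printed"
    hu_response_gain: float = 40.0  # HU darkening per unit volume loss

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["response"] = dataclasses.asdict(self.response)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "response" in d:
            d["response"] = ResponseParams(**d["response"])
        d["shape"] = tuple(d.get("shape", (64, 64, 40)))
        d["spacing"] = tuple(d.get("spacing", (4.0, 4.0, 5.0)))
        return cls(**d)


@dataclass
class SyntheticCase:
    """One phantom patient with images, plan metadata and planted truth."""

    case_id: str
    cancer_type: str
    prescription_gy: float
    n_fractions: int
    t_days: float
    target_region: str
    pre_ct: Grid3D
    labels: LabelGrid
    vessels: LabelGrid
    dose: Grid3D
    eqd2: Grid3D
    post_ct: Grid3D
    post_labels: LabelGrid
    post_vessels: LabelGrid
    truth_dvf: DisplacementField
    truth_dv: Grid3D

    def __post_init__(self) -> None:
        if not 50 <= self.prescription_gy <= 100:
            raise ValueError("prescription must lie in [50, 100] Gy")
        if not 10 <= self.n_fractions <= 28:
            raise ValueError("fraction number must lie in [10, 28]")
        if not T_RANGE_DAYS[0] <= self.t_days <= T_RANGE_DAYS[1]:
            raise ValueError("follow-up gap must lie in [79, 257] d")

    @property
    def liver_mask(self) -> np.ndarray:
        return self.labels.liver_mask()

    @property
    def post_liver_mask(self) -> np.ndarray:
        return self.post_labels.liver_mask()

    @property
    def scheme(self) -> FractionationScheme:
        return FractionationScheme(self.prescription_gy, self.n_fractions)


# ---------------------------------------------------------------------------
# Anatomy


def _smooth_noise(rng: np.random.Generator, shape, sigma_vox: float) -> np.ndarray:
    """Zero-mean, unit-std Gaussian-smoothed white noise."""
    n = ndi.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = n.std()
    return (n - n.mean()) / (sd if sd > 0 else 1.0)


def generate_anatomy(
    seed: int,
    shape: tuple[int, int, int] = (64, 64, 40),
    spacing: tuple[float, float, float] = (4.0, 4.0, 5.0),
) -> tuple[Grid3D, LabelGrid, LabelGrid]:
    """Generate (pre_ct, segment labels, vessel mask) for one phantom.

    The liver is a smooth randomly-perturbed superellipsoid occupying
    15-35 % of the field of view, partitioned through a hilum point into a
    caudate-like segment 1, left-lobe segments 2-4 and the (largest)
    right lobe (label 5).  A recursive binary vessel tree rooted at the
    hilum is rasterised inside the liver as a separate 0/1 mask.
    Deterministic given the seed.
    """
    if any(int(s) < 32 for s in shape):
        raise ValueError("shape must be at least 32 voxels per axis to host a liver")
    rng = np.random.default_rng(seed)
    geom = Geometry(tuple(shape), tuple(spacing), (0.0, 0.0, 0.0))
    sp = np.asarray(spacing, float)
    fov = np.asarray(shape, float) * sp
    coords = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij", sparse=True
    )

    # --- liver blob: perturbed superellipsoid, volume fraction pinned by quantile
    center = fov * (0.5 + rng.uniform(-0.04, 0.04, 3))
    semi = fov * np.array([0.33, 0.30, 0.34]) * rng.uniform(0.9, 1.1, 3)
    expo = rng.uniform(2.2, 2.8)
    q = sum((np.abs(c - mu) / a) ** expo for c, mu, a in zip(coords, center, semi))
    fld = q + 0.25 * _smooth_noise(rng, shape, sigma_vox=5.0)
    frac = rng.uniform(0.17, 0.30)
    thr = np.quantile(fld, frac)
    liver = fld < thr
    # largest connected component, closed and filled
    lab, n_cc = ndi.label(liver)
    if n_cc > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n_cc + 1))
        liver = lab == (1 + int(np.argmax(sizes)))
    liver = ndi.binary_closing(liver, iterations=2)
    liver = ndi.binary_fill_holes(liver)
    vol_frac = liver.mean()
    if not 0.10 <= vol_frac <= 0.40:
        raise RuntimeError(f"liver occupies {vol_frac:.0%} of the volume; regenerate")

    liver_idx = np.argwhere(liver)
    liver_mm = liver_idx * sp
    centroid = liver_mm.mean(axis=0)

    # hilum: antero-medial of centroid, snapped into the liver
    hilum = centroid + np.array([-0.10, -0.15, 0.0]) * (liver_mm.max(0) - liver_mm.min(0))
    hilum = liver_mm[np.argmin(((liver_mm - hilum) ** 2).sum(1))]

    # --- partition: caudate ellipsoid, then an oblique right/left plane,
    # then tertiles along an oblique axis for segments 2/3/4
    labels = np.zeros(shape, dtype=np.int32)
    pt = np.stack(np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                              indexing="ij"), axis=-1)
    caud_center = hilum + np.array([0.0, 0.24, 0.10]) * fov * rng.uniform(0.8, 1.1)
    caud_center = liver_mm[np.argmin(((liver_mm - caud_center) ** 2).sum(1))]
    caud_semi = np.array([0.13, 0.12, 0.13]) * (liver_mm.max(0) - liver_mm.min(0)) / 2
    caud = (((pt - caud_center) / caud_semi) ** 2).sum(-1) < 1.0

    n1 = np.array([1.0, 0.0, 0.0]) + rng.uniform(-0.25, 0.25, 3) * np.array([0, 1, 1])
    n1 /= np.linalg.norm(n1)
    d1 = (pt - hilum) @ n1
    d1_liver = d1[liver & ~caud]
    right_frac = rng.uniform(0.55, 0.65)
    split1 = np.quantile(d1_liver, 1.0 - right_frac)

    n2 = np.array([0.0, 0.4, 1.0]) + rng.uniform(-0.2, 0.2, 3)
    n2 /= np.linalg.norm(n2)
    d2 = (pt - hilum) @ n2

    body = liver & ~caud
    right = body & (d1 >= split1)
    left = body & ~right
    d2_left = d2[left]
    t1, t2 = np.quantile(d2_left, [1 / 3, 2 / 3])
    labels[left & (d2 < t1)] = 2
    labels[left & (d2 >= t1) & (d2 < t2)] = 3
    labels[left & (d2 >= t2)] = 4
    labels[right] = 5
    labels[liver & caud] = 1
    assert set(np.unique(labels[liver])) <= {1, 2, 3, 4, 5}

    # --- vessel tree: recursive binary tree rooted at the hilum
    vessels = np.zeros(shape, dtype=bool)

    def _capsule(p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
        # never rasterize thinner than one voxel or branches vanish on
        # coarse lattices
        radius = max(radius, float(sp.min()))
        lo = np.maximum(0, np.floor((np.minimum(p0, p1) - radius) / sp).astype(int))
        hi = np.minimum(shape, np.ceil((np.maximum(p0, p1) + radius) / sp).astype(int) + 1)
        if np.any(hi <= lo):
            return
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        local = pt[sl]
        seg = p1 - p0
        L2 = float(seg @ seg)
        t = np.clip(((local - p0) @ seg) / (L2 if L2 > 0 else 1.0), 0, 1)
        d = np.linalg.norm(local - (p0 + t[..., None] * seg), axis=-1)
        vessels[sl] |= d <= radius

    def _grow(p0: np.ndarray, direction: np.ndarray, length: float, radius: float, depth: int) -> None:
        target = liver_mm[rng.integers(len(liver_mm))]
        direction = 0.5 * direction + 0.5 * (target - p0) / (np.linalg.norm(target - p0) + 1e-9)
        direction /= np.linalg.norm(direction)
        p1 = p0 + direction * length
        p1 = np.clip(p1, liver_mm.min(0), liver_mm.max(0))
        _capsule(p0, p1, radius)
        if depth <= 0:
            return
        for _ in range(2):
            perturb = rng.normal(0, 0.45, 3)
            child = direction + perturb
            child /= np.linalg.norm(child)
            _grow(p1, child, length * 0.72, max(radius * 0.75, min(sp) * 0.45), depth - 1)

    trunk_dir = (centroid - hilum) / (np.linalg.norm(centroid - hilum) + 1e-9)
    extent = liver_mm.max(0) - liver_mm.min(0)
    trunk_len = 0.35 * float(extent.mean())
    # portal-like and hepatic-like trees give the interior boundary
    # conditions their spatial coverage
    _grow(hilum.astype(float), trunk_dir, trunk_len, radius=4.0, depth=5)
    second = trunk_dir + rng.normal(0, 0.6, 3)
    second /= np.linalg.norm(second)
    _grow(hilum.astype(float), second, 0.8 * trunk_len, radius=3.2, depth=5)
    # segmental branches: portal anatomy serves every segment, which is
    # also what lets vessel-driven boundary conditions reach each region
    for seg_label in (2, 3, 4, 5):
        seg_pts = np.argwhere(labels == seg_label) * sp
        if len(seg_pts) == 0:
            continue
        seg_c = seg_pts.mean(axis=0)
        d = seg_c - hilum
        dist = np.linalg.norm(d)
        if dist < 1e-6:
            continue
        _grow(hilum.astype(float), d / dist, 0.55 * dist, radius=2.8, depth=3)
    vessels &= liver

    # --- CT intensities
    ct = -50.0 + 30.0 * _smooth_noise(rng, shape, sigma_vox=3.0)
    liver_tex = 90.0 + 10.0 * _smooth_noise(rng, shape, sigma_vox=2.0)
    ct[liver] = liver_tex[liver]
    ct[vessels] = 140.0 + 5.0 * _smooth_noise(rng, shape, sigma_vox=1.5)[vessels]

    pre_ct = Grid3D(ct, geom.spacing, geom.origin)
    seg_grid = LabelGrid(labels, geom.spacing, geom.origin)
    vessel_grid = LabelGrid(
        vessels.astype(np.int32), geom.spacing, geom.origin, legend={0: "background", 1: "vessel"}
    )
    return pre_ct, seg_grid, vessel_grid


# ---------------------------------------------------------------------------
# Dose plan


def generate_plan(
    labels: LabelGrid,
    target_label: int,
    prescription_gy: float,
    n_fractions: int,
    seed: int,
) -> Grid3D:
    """IMRT-like planned physical dose (Gy).

    An ellipsoidal GTV-like focus inside the target region receives exactly
    the prescription; dose decays outward as an anisotropic Gaussian, and a
    low-dose bath (5-15 Gy) fills a beam corridor through the focus.  The
    maximum never exceeds 1.1 x prescription (falloff and bath combine by
    maximum, not sum).
    """
    region = labels.labels == target_label
    if region.sum() < 8:
        raise ValueError(f"target region {target_label} too small to host a focus")
    rng = np.random.default_rng(seed)
    sp = np.asarray(labels.spacing, float)
    shape = labels.shape

    # focus at one of the deepest interior points of the target region so
    # the Gaussian falloff stays regional
    depth = ndi.distance_transform_edt(region, sampling=sp)
    cut = np.quantile(depth[region], 0.92)
    pool = np.argwhere(depth >= max(cut, depth.max() * 0.5))
    focus = pool[rng.integers(len(pool))] * sp

    pt = np.stack(np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, sp)),
                              indexing="ij"), axis=-1)
    # GTV scaled to the target region so regional mean doses span the
    # clinically meaningful range around the 50 Gy split
    region_idx = np.argwhere(region)
    region_extent = (region_idx.max(0) - region_idx.min(0) + 1) * sp
    gtv_semi = np.clip(0.28 * region_extent, 12.0, 35.0) * rng.uniform(0.85, 1.15, 3)
    qn = np.sqrt((((pt - focus) / gtv_semi) ** 2).sum(-1))
    sigma_falloff = 18.0  # mm
    r_gm = float(np.prod(gtv_semi) ** (1 / 3))
    d_mm = np.maximum(qn - 1.0, 0.0) * r_gm
    dose = prescription_gy * np.exp(-0.5 * (d_mm / sigma_falloff) ** 2)

    beam = rng.normal(0, 1, 3)
    beam /= np.linalg.norm(beam)
    rel = pt - focus
    rho = np.linalg.norm(rel - (rel @ beam)[..., None] * beam, axis=-1)
    bath = rng.uniform(5.0, 15.0) * np.exp(-0.5 * (rho / 30.0) ** 2)
    dose = np.maximum(dose, bath)
    return Grid3D(dose, labels.spacing, labels.origin)


# ---------------------------------------------------------------------------
# Planted response and ground-truth deformation


def _poisson_dirichlet(f: np.ndarray, spacing, lam_min: float = 1e-10) -> np.ndarray:
    """Solve grad . grad phi = f (wide central-difference stencil) with a
    zero Dirichlet boundary via a type-I DST fast solver.

    The wide (2h) stencil is chosen because the Jacobian of the resulting
    field u = grad phi is later measured with the same central differences:
    using the matching discrete operator makes the measured divergence
    reproduce f exactly in the interior.  The stencil's near-null
    mid-frequency modes are projected out; the target fields are smooth,
    so their content there is negligible.
    """
    interior = f[1:-1, 1:-1, 1:-1].astype(np.float64)
    n = interior.shape
    fh = sfft.dstn(interior, type=1)
    eig = 0.0
    for ax, (m, h) in enumerate(zip(n, spacing)):
        k = np.arange(1, m + 1)
        lam = (2.0 * np.cos(2.0 * np.pi * k / (m + 1)) - 2.0) / (4.0 * h * h)
        sh = [1, 1, 1]
        sh[ax] = m
        eig = eig + lam.reshape(sh)
    keep = np.abs(eig) > lam_min
    phi_int = sfft.idstn(np.where(keep, fh / np.where(keep, eig, 1.0), 0.0), type=1)
    phi = np.zeros_like(f, dtype=np.float64)
    phi[1:-1, 1:-1, 1:-1] = phi_int
    return phi


def _dvf_from_volume_change(
    g: np.ndarray, geom: Geometry, n_corrections: int = 3
) -> DisplacementField:
    """Displacement field u = grad(phi) whose Jacobian matches 1+g.

    Starts from the small-strain identity div u = log(1+g) and then
    applies fixed-point corrections against the *measured*
    central-difference Jacobian determinant, which absorbs most of the
    second-order determinant terms at large |g|; the generator still
    clips g to [-0.6, 0.4] where the construction is well conditioned.
    """
    from .jacobian import jacobian_determinant

    target = 1.0 + g
    f = np.log1p(g)
    u = None
    for _ in range(1 + n_corrections):
        phi = _poisson_dirichlet(f, geom.spacing)
        u = np.stack(
            [np.gradient(phi, geom.spacing[ax], axis=ax) for ax in range(3)], axis=-1
        )
        det = jacobian_determinant(
            DisplacementField(u, geom.spacing, geom.origin)
        ).values
        f = f + np.log(target / np.clip(det, 0.05, None))
    return DisplacementField(u, geom.spacing, geom.origin)


def invert_dvf(dvf: DisplacementField, n_iter: int = 10) -> DisplacementField:
    """Fixed-point inverse of x -> x + u(x): returns v with v(y) = -u(y + v(y))."""
    sp = np.asarray(dvf.spacing, float)
    base = np.stack(np.meshgrid(*(np.arange(n, dtype=float) for n in dvf.shape),
                                indexing="ij"), axis=-1)
    v = np.zeros_like(dvf.u)
    for _ in range(n_iter):
        idx = base + v / sp  # index of y + v(y)
        coords = [idx[..., ax] for ax in range(3)]
        u_at = np.stack(
            [ndi.map_coordinates(dvf.u[..., ax], coords, order=1, mode="nearest")
             for ax in range(3)], axis=-1)
        v = -u_at
    return DisplacementField(v, dvf.spacing, dvf.origin)


def warp_volume(
    vol: Grid3D | LabelGrid, inverse_dvf: DisplacementField, interp: str = "linear"
) -> Grid3D | LabelGrid:
    """Forward-warp a pre volume: out(y) = vol(y + v(y)) with v the inverse field."""
    sp = np.asarray(inverse_dvf.spacing, float)
    base = np.stack(np.meshgrid(*(np.arange(n, dtype=float) for n in inverse_dvf.shape),
                                indexing="ij"), axis=-1)
    idx = base + inverse_dvf.u / sp
    coords = [idx[..., ax] for ax in range(3)]
    if isinstance(vol, LabelGrid):
        out = ndi.map_coordinates(vol.labels, coords, order=0, mode="constant", cval=0)
        return LabelGrid(out.astype(vol.labels.dtype), vol.spacing, vol.origin, legend=vol.legend)
    order = {"linear": 1, "nearest": 0}[interp]
    out = ndi.map_coordinates(vol.values.astype(float), coords, order=order,
                              mode="nearest")
    return Grid3D(out, vol.spacing, vol.origin)


def plant_response(
    labels: LabelGrid,
    g_raw: np.ndarray,
    pre_ct: Grid3D,
    vessels: LabelGrid,
    hu_response_gain: float = 40.0,
    smoothing_vox: float = 0.9,
) -> tuple[Grid3D, DisplacementField, Grid3D, LabelGrid, LabelGrid]:
    """Plant an arbitrary volume-change field and derive all post data.

    ``g_raw`` is clipped-and-masked volume change (0 outside liver).  A
    half-voxel smoothing is applied inside the liver before the Poisson
    construction so the prescribed divergence is resolvable on the lattice;
    the returned truth map is that resolvable field.  Returns
    (truth_dv, truth_dvf, post_ct, post_labels, post_vessels).
    """
    liver = labels.liver_mask()
    g = np.where(liver, g_raw, 0.0)
    if not np.all(np.isfinite(g)):
        raise ValueError("planted response contains non-finite values")
    if g.min() <= -1.0:
        raise ValueError("planted response must stay above -1")
    if smoothing_vox > 0:
        # normalized convolution: smooth within the liver without diluting
        # the response toward the outside zeros (which would bias regional
        # means); needed only when the response has sub-voxel-sharp features
        w = ndi.gaussian_filter(liver.astype(np.float64), smoothing_vox)
        g = ndi.gaussian_filter(g, smoothing_vox) / np.maximum(w, 1e-6)
        g = np.where(liver, g, 0.0)
    geom = labels.geometry
    dvf = _dvf_from_volume_change(g, geom)
    truth_dv = Grid3D(g, geom.spacing, geom.origin)

    inv = invert_dvf(dvf)
    post_labels = warp_volume(labels, inv)
    post_vessels = warp_volume(vessels, inv)
    post_ct_vals = np.asarray(warp_volume(pre_ct, inv).values)
    # mild HU darkening in atrophic zones gives the predictor texture cues
    post_liver = post_labels.liver_mask()
    dv_in_post = warp_volume(truth_dv, inv).values
    post_ct_vals = post_ct_vals + hu_response_gain * np.where(post_liver, dv_in_post, 0.0)
    post_ct = Grid3D(post_ct_vals, geom.spacing, geom.origin)
    return truth_dv, dvf, post_ct, post_labels, post_vessels


def generate_response(
    labels: LabelGrid,
    eqd2: Grid3D,
    t_days: float,
    params: ResponseParams,
    seed: int,
    pre_ct: Grid3D,
    vessels: LabelGrid,
    hu_response_gain: float = 40.0,
) -> tuple[Grid3D, DisplacementField, Grid3D, LabelGrid, LabelGrid]:
    """Planted dose-driven response; see the module docstring for the model."""
    if not np.all(np.isfinite(eqd2.values)):
        raise ValueError("EQD2 grid contains non-finite values")
    if eqd2.shape != labels.shape:
        raise ValueError("EQD2 grid must share the label geometry")
    rng = np.random.default_rng(seed)
    liver = labels.liver_mask()
    e = np.asarray(eqd2.values, float)

    s_i = float(rng.lognormal(0.0, params.patient_sd)) if params.patient_sd > 0 else 1.0
    atrophied_frac = float((e[liver] > 50.0).mean())
    gate = 1.0 / (1.0 + np.exp((e - params.dose_threshold_gy) / params.threshold_width_gy))
    time_factor = (t_days / T_MEAN_DAYS) ** params.time_coupling
    if np.isfinite(params.max_atrophy):
        atrophy = params.max_atrophy * -np.expm1(-params.slope_per_gy * e / params.max_atrophy)
    else:
        atrophy = params.slope_per_gy * e
    hyper = params.compensation_gain * atrophied_frac * gate
    proximity = 0.0
    if (params.vessel_sparing > 0 or params.vascular_hypertrophy > 0
            or params.baseline_remodeling > 0):
        d_vessel = ndi.distance_transform_edt(
            ~(vessels.labels > 0), sampling=labels.spacing
        )
        proximity = np.clip(1.0 - d_vessel / params.vessel_sparing_radius_mm, 0.0, 1.0)
        # well-perfused tissue both resists atrophy and regenerates more
        atrophy = atrophy * (1.0 - params.vessel_sparing * proximity)
        hyper = hyper * (1.0 + params.vascular_hypertrophy * proximity)
    remodeling = 0.0
    if params.capsule_enhancement > 0 or params.baseline_remodeling > 0:
        depth = ndi.distance_transform_edt(liver, sampling=labels.spacing)
        subcapsular = np.clip(1.0 - depth / params.capsule_depth_mm, 0.0, 1.0)
        if params.capsule_enhancement > 0:
            # subcapsular tissue is the most vulnerable to volume loss
            atrophy = atrophy * (1.0 + params.capsule_enhancement * subcapsular)
        if params.baseline_remodeling > 0:
            # dose-independent remodeling over the follow-up interval:
            # perivascular regeneration against subcapsular thinning,
            # zero-mean over the liver so total volume is dose-driven
            pattern = 0.5 * proximity - subcapsular
            pattern = pattern - pattern[liver].mean()
            remodeling = params.baseline_remodeling * pattern
    det = s_i * (-atrophy + hyper + remodeling) * time_factor
    if params.voxel_noise_sd > 0:
        det = det + params.voxel_noise_sd * _smooth_noise(rng, labels.shape, sigma_vox=2.5)
    g = np.clip(det, params.clip_lo, params.clip_hi)
    return plant_response(
        labels, np.where(liver, g, 0.0), pre_ct, vessels, hu_response_gain,
        smoothing_vox=params.construction_smoothing_vox,
    )


# ---------------------------------------------------------------------------
# Cohort


def _draw_truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def generate_cohort(
    n_cases: int,
    seed: int,
    config: CohortConfig | None = None,
    out_dir: str | Path | None = None,
) -> list[SyntheticCase]:
    """Generate a deterministic phantom cohort (optionally written to disk).

    Cancer types, prescriptions and fraction numbers are drawn from the
    target cohort's empirical distributions; the follow-up gap from
    N(147, 36) d truncated to [79, 257] d.  The irradiated region is drawn
    among segments 2-4 and the right lobe.
    """
    if n_cases < 10:
        raise ValueError("cohort needs at least 10 cases")
    config = config or CohortConfig()
    if config.eqd2_mode not in ("as_printed", "standard"):
        raise ValueError(f"invalid eqd2 mode {config.eqd2_mode!r}")
    master = np.random.default_rng(seed)
    presc_p = np.asarray(PRESCRIPTION_COUNTS, float)
    presc_p /= presc_p.sum()
    frac_p = np.asarray(FRACTION_COUNTS, float)
    frac_p /= frac_p.sum()

    cases = []
    for i in range(n_cases):
        sub = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub)
        cancer = CANCER_TYPES[rng.choice(len(CANCER_TYPES), p=CANCER_PROBS)]
        presc = float(PRESCRIPTIONS_GY[rng.choice(len(PRESCRIPTIONS_GY), p=presc_p)])
        nfx = int(FRACTION_NUMBERS[rng.choice(len(FRACTION_NUMBERS), p=frac_p)])
        t_days = _draw_truncnorm(rng, T_MEAN_DAYS, T_SD_DAYS, *T_RANGE_DAYS)
        target_label = int(rng.choice([2, 3, 4, 5], p=[0.18, 0.18, 0.18, 0.46]))

        for attempt in range(5):
            try:
                pre_ct, labels, vessels = generate_anatomy(
                    int(rng.integers(0, 2**31 - 1)), config.shape, config.spacing
                )
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError("anatomy generation failed repeatedly")
        dose = generate_plan(labels, target_label, presc, nfx, int(rng.integers(0, 2**31 - 1)))
        scheme = FractionationScheme(presc, nfx)
        eqd2 = eqd2_map(dose, scheme, mode=config.eqd2_mode)
        truth_dv, truth_dvf, post_ct, post_labels, post_vessels = generate_response(
            labels, eqd2, t_days, config.response, int(rng.integers(0, 2**31 - 1)),
            pre_ct, vessels, config.hu_response_gain,
        )
        region_name = {2: "seg2", 3: "seg3", 4: "seg4", 5: "right_lobe"}[target_label]
        case = SyntheticCase(
            case_id=f"case{i:03d}",
            cancer_type=cancer,
            prescription_gy=presc,
            n_fractions=nfx,
            t_days=t_days,
            target_region=region_name,
            pre_ct=pre_ct,
            labels=labels,
            vessels=vessels,
            dose=dose,
            eqd2=eqd2,
            post_ct=post_ct,
            post_labels=post_labels,
            post_vessels=post_vessels,
            truth_dvf=truth_dvf,
            truth_dv=truth_dv,
        )
        cases.append(case)
        if out_dir is not None:
            write_case(case, Path(out_dir) / case.case_id)

    if out_dir is not None:
        manifest = {
            "n_cases": n_cases,
            "seed": seed,
            "config": config.to_json(),
            "cases": [
                {
                    "case_id": c.case_id,
                    "cancer_type": c.cancer_type,
                    "prescription_gy": c.prescription_gy,
                    "n_fractions": c.n_fractions,
                    "t_days": c.t_days,
                    "target_region": c.target_region,
                }
                for c in cases
            ],
        }
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cases


_CASE_VOLUMES = {
    "pre_ct": "pre_ct.nii.gz",
    "dose": "dose.nii.gz",
    "eqd2": "eqd2.nii.gz",
    "post_ct": "post_ct.nii.gz",
    "truth_dv": "truth_dv.nii.gz",
}
_CASE_LABELS = {
    "labels": "labels.nii.gz",
    "vessels": "vessels.nii.gz",
    "post_labels": "post_labels.nii.gz",
    "post_vessels": "post_vessels.nii.gz",
}


def write_case(case: SyntheticCase, case_dir: str | Path) -> None:
    """Write one case as NIfTI volumes plus a JSON metadata sidecar."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _CASE_VOLUMES.items():
        write_volume(getattr(case, attr), case_dir / fname)
    for attr, fname in _CASE_LABELS.items():
        write_volume(getattr(case, attr), case_dir / fname)
    write_dvf(case.truth_dvf, case_dir / "truth_dvf.nii.gz")
    meta = {
        "case_id": case.case_id,
        "cancer_type": case.cancer_type,
        "prescription_gy": case.prescription_gy,
        "n_fractions": case.n_fractions,
        "t_days": case.t_days,
        "target_region": case.target_region,
    }
    (case_dir / "meta.json").write_text(json.dumps(meta, indent=2))


def load_case(case_dir: str | Path) -> SyntheticCase:
    """Load a case previously written by :func:`write_case`."""
    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "meta.json").read_text())
    vols = {attr: read_volume(case_dir / fname) for attr, fname in _CASE_VOLUMES.items()}
    labs = {attr: read_volume(case_dir / fname) for attr, fname in _CASE_LABELS.items()}
    return SyntheticCase(
        truth_dvf=read_dvf(case_dir / "truth_dvf.nii.gz"), **meta, **vols, **labs
    )
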