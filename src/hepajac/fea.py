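"""Linear-elastic finite-element analysis on tetrahedral meshes.

Small-strain isotropic elasticity with linear (constant-strain) tetrahedral
elements and Dirichlet (prescribed-displacement) boundary conditions.  With
pure Dirichlet data and no body force the solution is independent of the
Young's modulus (it scales both sides of the system), so only the Poisson
ratio shapes the interpolation; near-incompressible soft-tissue defaults
are used.  Linear tets reproduce affine displacement fields exactly (the
patch test), which the test suite exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .mesh import TetMesh

__all__ = ["Material", "BoundaryConditionSet", "solve_fea", "element_stiffness"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material: E in kPa, Poisson ratio dimensionless."""

    youngs_modulus: float = 2.0
    poisson_ratio: float = 0.45

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        e, nu = self.youngs_modulus, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        return lam, mu


@dataclass
class BoundaryConditionSet:
    """Prescribed nodal displacements (mm): node index -> 3-vector."""

    entries: dict[int, np.ndarray] = field(default_factory=dict)
    source: dict[int, str] = field(default_factory=dict)

    def set(self, node: int, displacement, source: str = "surface") -> None:
        self.entries[int(node)] = np.asarray(displacement, dtype=float)
        self.source[int(node)] = source

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self, mesh: TetMesh) -> None:
        if any(not 0 <= i < mesh.n_nodes for i in self.entries):
            raise ValueError("boundary condition on a node index outside the mesh")
        if len(self.entries) < 4:
            raise ValueError("need at least 4 constrained nodes to remove rigid modes")
        pts = mesh.nodes[sorted(self.entries)]
        centred = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-6) < 3:
            raise ValueError("constrained nodes are coplanar; rigid modes remain")


def element_stiffness(coords: np.ndarray, material: Material) -> np.ndarray:
    """Dense 12x12 stiffness of one linear tet with corner coordinates (4,3)."""
    lam, mu = material.lame
    d = np.array(
        [
            [lam + 2 * mu, lam, lam, 0, 0, 0],
            [lam, lam + 2 * mu, lam, 0, 0, 0],
            [lam, lam, lam + 2 * mu, 0, 0, 0],
            [0, 0, 0, mu, 0, 0],
            [0, 0, 0, 0, mu, 0],
            [0, 0, 0, 0, 0, mu],
        ]
    )
    m = np.column_stack([np.ones(4), coords])
    vol = np.linalg.det(m) / 6.0
    if vol <= 0:
        raise ValueError("element has non-positive volume")
    grads = np.linalg.inv(m)[1:, :]  # (3, 4): d phi_a / d x_i
    b = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a]
        b[:, 3 * a : 3 * a + 3] = np.array(
            [
                [gx, 0, 0],
                [0, gy, 0],
                [0, 0, gz],
                [gy, gx, 0],
                [0, gz, gy],
                [gz, 0, gx],
            ]
        )
    return vol * b.T @ d @ b


def _assemble(mesh: TetMesh, material: Material) -> sparse.csr_matrix:
    """Global sparse stiffness, vectorised over elements.

    All tets in the structured mesh share a handful of congruent geometries,
    but assembly is generic: per-element B matrices are built in a batch.
    """
    lam, mu = material.lame
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] = lam + 2 * mu
    d[np.arange(3, 6), np.arange(3, 6)] = mu

    tets = mesh.tets
    p = mesh.nodes[tets]  # (M,4,3)
    m = np.concatenate([np.ones((len(tets), 4, 1)), p], axis=2)  # (M,4,4)
    vol = np.linalg.det(m) / 6.0
    if np.any(vol <= 0):
        raise ValueError("mesh contains non-positive tet volumes")
    minv = np.linalg.inv(m)
    grads = minv[:, 1:, :]  # (M, 3, 4)

    bmat = np.zeros((len(tets), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, 0, a], grads[:, 1, a], grads[:, 2, a]
        c = 3 * a
        bmat[:, 0, c] = gx
        bmat[:, 1, c + 1] = gy
        bmat[:, 2, c + 2] = gz
        bmat[:, 3, c], bmat[:, 3, c + 1] = gy, gx
        bmat[:, 4, c + 1], bmat[:, 4, c + 2] = gz, gy
        bmat[:, 5, c], bmat[:, 5, c + 2] = gz, gx
    ke = np.einsum("m,mia,ij,mjb->mab", vol, bmat, d, bmat, optimize=True)

    dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tets), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    k = sparse.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    )
    return k.tocsr()


def solve_fea(
    mesh: TetMesh,
    bcs: BoundaryConditionSet,
    material: Material | None = None,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Nodal displacements (mm) under prescribed-displacement conditions.

    Constrained nodes satisfy their prescription exactly; free nodes solve
    the reduced symmetric positive-definite system to a relative residual
    of ``rtol`` (verified, not assumed).
    """
    material = material or Material()
    bcs.validate(mesh)
    k = _assemble(mesh, material)
    n_dof = 3 * mesh.n_nodes

    fixed_nodes = np.array(sorted(bcs.entries), dtype=np.int64)
    u = np.zeros(n_dof)
    for node in fixed_nodes:
        u[3 * node : 3 * node + 3] = bcs.entries[int(node)]
    fixed_dof = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    free_dof = np.setdiff1d(np.arange(n_dof), fixed_dof, assume_unique=False)
    if free_dof.size == 0:
        return u.reshape(-1, 3)

    k_ff = k[free_dof][:, free_dof]
    rhs = -k[free_dof][:, fixed_dof] @ u[fixed_dof]
    try:
        u_f = spsolve(k_ff.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - singular assembly
        raise RuntimeError(f"FEA solve failed: {exc}") from exc
    res = np.linalg.norm(k_ff @ u_f - rhs)
    ref = np.linalg.norm(rhs)
    if ref > 0 and res / ref > rtol:
        raise RuntimeError(
            f"FEA relative residual {res / ref:.2e} exceeds {rtol:.0e}; "
            "system may be ill-conditioned or insufficiently constrained"
        )
    u[free_dof] = u_f
    return u.reshape(-1, 3)
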