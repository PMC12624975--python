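"""Static hyperelastic finite elements for implant micromotion.

Solves the static boundary-value problem of a rigid (or linear-elastic)
silicon array displacing laterally inside a one-term Ogden tissue block.
The tissue strain-energy density is

    Psi = (mu1/alpha1) * (l1^-a1 + l2^-a1 + l3^-a1 - 3) + (1/d1) * (J-1)^2

with principal stretches l_i and volume ratio J = det F, using the cortical
parameters mu1 = 150.5 Pa, alpha1 = 19, d1 = 6.65e-5 1/Pa.  Written with
the negative exponent this is a standard one-term Ogden material with
ground-state shear modulus mu = mu1*alpha1/2 ~ 1.43 kPa and bulk modulus
kappa = 2/d1 ~ 30 kPa (nearly incompressible, kappa/mu ~ 21).  Two stretch
conventions are supported: ``raw`` applies the deviatoric term to the raw
principal stretches exactly as written; ``isochoric`` (default) applies it
to the volume-corrected stretches lbar_i = J^(-1/3) l_i, the form used by
the one-term Ogden models of major commercial solvers.

Discretization: 10-node (quadratic) tetrahedra, total-Lagrangian
formulation, 4-point Gauss rule, Newton iteration with adaptive load
stepping, a consistent boundary-condition predictor, chord-style tangent
reuse and a backtracking line search.  Linear systems are solved by CG
with a two-level p-multigrid preconditioner (linear-subspace coarse LU +
Chebyshev-Jacobi smoothing) that is frozen across iterations, which keeps
repeated Newton steps cheap on a single CPU.  All lengths in um, stresses
in Pa (forces then come out in pN).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SolidModel
from .meshing import Mesh, MeshSpec, REGION_ARRAY, REGION_TISSUE, TET10_EDGES

__all__ = [
    "OgdenMaterial",
    "ElasticMaterial",
    "BoundaryConditions",
    "SolverParams",
    "DisplacementField",
    "StrainField",
    "SolverError",
    "ogden_energy",
    "pk1_stress",
    "pk1_tangent_fd",
    "solve_static",
    "strain_from_displacement",
    "von_mises_from_principal",
    "StaticProblem",
    "PMultigridPreconditioner",
    "interpolate_displacement",
    "solve_submodel",
    "refine_table_with_submodels",
    "run_micromotion_case",
    "electrode_table_for_displacement",
    "mesh_convergence_study",
    "MicromotionResult",
]


class SolverError(RuntimeError):
    """Newton solve failed to converge."""


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OgdenMaterial:
    """One-term Ogden solid (negative-exponent form) for cortical tissue."""

    mu1: float = 150.5  # Pa
    alpha1: float = 19.0
    d1: float = 6.65e-5  # 1/Pa
    stretch_convention: str = "isochoric"  # or "raw"

    def __post_init__(self):
        if self.mu1 <= 0 or self.d1 <= 0:
            raise ValueError("mu1 and d1 must be positive")
        if self.stretch_convention not in ("raw", "isochoric"):
            raise ValueError("stretch_convention must be 'raw' or 'isochoric'")

    @property
    def shear_modulus(self) -> float:
        """Ground-state shear modulus mu = mu1*alpha1/2."""
        return self.mu1 * self.alpha1 / 2.0

    @property
    def bulk_modulus(self) -> float:
        """Ground-state bulk modulus kappa = 2/d1."""
        return 2.0 / self.d1


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic elastic solid (silicon default: 200 GPa, nu = 0.278).

    ``model`` selects the finite-strain extension: ``"stvk"`` (St. Venant-
    Kirchhoff, for the silicon region in elastic mode) or ``"linear"``
    (stress linear in the displacement gradient -- the small-strain
    solution, used as a verification oracle).
    """

    youngs_modulus: float = 2.0e11
    poisson_ratio: float = 0.278
    model: str = "stvk"

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson's ratio must be in [0, 0.5)")
        if self.model not in ("stvk", "linear"):
            raise ValueError("model must be 'stvk' or 'linear'")

    @property
    def lame_lambda(self) -> float:
        e, nu = self.youngs_modulus, self.poisson_ratio
        return e * nu / ((1 + nu) * (1 - 2 * nu))

    @property
    def lame_mu(self) -> float:
        return self.youngs_modulus / (2 * (1 + self.poisson_ratio))

    @classmethod
    def from_shear_bulk(cls, mu: float, kappa: float, model: str = "linear"
                        ) -> "ElasticMaterial":
        e = 9 * kappa * mu / (3 * kappa + mu)
        nu = (3 * kappa - 2 * mu) / (2 * (3 * kappa + mu))
        return cls(youngs_modulus=e, poisson_ratio=nu, model=model)


def ogden_energy(stretches, J, material: OgdenMaterial):
    """Strain-energy density (Pa) from principal stretches and J.

    ``stretches`` has shape (..., 3).  The volumetric term uses the given J;
    in the isochoric convention the deviatoric term uses
    lbar = J^(-1/3) * l.  Exactly zero at the reference state.
    """
    lam = np.asarray(stretches, dtype=float)
    J = np.asarray(J, dtype=float)
    if np.any(lam <= 0) or np.any(J <= 0):
        raise ValueError("principal stretches and J must be positive")
    if material.stretch_convention == "isochoric":
        lam = lam * J[..., None] ** (-1.0 / 3.0)
    mu, a, d = material.mu1, material.alpha1, material.d1
    dev = (mu / a) * (np.sum(lam ** (-a), axis=-1) - 3.0)
    vol = (1.0 / d) * (J - 1.0) ** 2
    return dev + vol


def _ogden_principal_forces(lam: np.ndarray, J: np.ndarray,
                            m: OgdenMaterial) -> np.ndarray:
    """dPsi/dl_a for the Ogden energy, shape (..., 3)."""
    mu, a, d = m.mu1, m.alpha1, m.d1
    if m.stretch_convention == "raw":
        dev = -mu * lam ** (-a - 1.0)
    else:
        lbar = lam * J[..., None] ** (-1.0 / 3.0)
        pow_ = lbar ** (-a)
        # d/dl_a of (mu/a) sum lbar^-a  (lbar depends on all stretches via J)
        dev = (mu / lam) * (-pow_ + np.sum(pow_, axis=-1, keepdims=True) / 3.0)
    vol = (2.0 / d) * (J - 1.0)[..., None] * (J[..., None] / lam)
    return dev + vol


def _material_energy_F(F: np.ndarray, mat) -> np.ndarray:
    """Energy density from deformation gradients, batched (..., 3, 3)."""
    if isinstance(mat, OgdenMaterial):
        C = np.swapaxes(F, -1, -2) @ F
        lam2 = np.linalg.eigvalsh(C)
        lam = np.sqrt(np.maximum(lam2, 1e-300))
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise SolverError("element inversion: det(F) <= 0")
        return ogden_energy(lam, J, mat)
    lam_l, mu_l = mat.lame_lambda, mat.lame_mu
    if mat.model == "stvk":
        C = np.swapaxes(F, -1, -2) @ F
        E = 0.5 * (C - np.eye(3))
    else:
        E = 0.5 * (F + np.swapaxes(F, -1, -2)) - np.eye(3)
    trE = np.trace(E, axis1=-2, axis2=-1)
    return 0.5 * lam_l * trE**2 + mu_l * np.einsum("...ij,...ij->...", E, E)


def pk1_stress(F: np.ndarray, mat) -> np.ndarray:
    """First Piola-Kirchhoff stress, batched over leading axes.

    For the Ogden material the stress is assembled in the principal frame of
    C; for elastic materials from the St. Venant-Kirchhoff or linearized
    law.  Raises :class:`SolverError` on non-positive det(F).
    """
    F = np.asarray(F, dtype=float)
    if isinstance(mat, OgdenMaterial):
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise SolverError("element inversion: det(F) <= 0")
        C = np.swapaxes(F, -1, -2) @ F
        lam2, N = np.linalg.eigh(C)
        lam = np.sqrt(np.maximum(lam2, 1e-300))
        dpsi = _ogden_principal_forces(lam, J, mat)
        # 2nd PK: S = sum_a (dpsi_a / l_a) N_a N_a^T
        coef = dpsi / lam
        S = np.einsum("...a,...ia,...ja->...ij", coef, N, N)
        return F @ S
    lam_l, mu_l = mat.lame_lambda, mat.lame_mu
    eye = np.eye(3)
    if mat.model == "stvk":
        C = np.swapaxes(F, -1, -2) @ F
        E = 0.5 * (C - eye)
        trE = np.trace(E, axis1=-2, axis2=-1)[..., None, None]
        S = lam_l * trE * eye + 2 * mu_l * E
        return F @ S
    # linear small-strain law: P := C : sym(grad u)
    eps = 0.5 * (F + np.swapaxes(F, -1, -2)) - eye
    tre = np.trace(eps, axis1=-2, axis2=-1)[..., None, None]
    return lam_l * tre * eye + 2 * mu_l * eps


def _pk1_tangent_fwd(F: np.ndarray, mat, h: float = 1e-7) -> np.ndarray:
    """Forward-difference material tangent (assembly kernel; 10 stress
    evaluations instead of 18)."""
    F = np.asarray(F, dtype=float)
    P0 = pk1_stress(F, mat)
    out = np.empty(F.shape[:-2] + (3, 3, 3, 3))
    for k in range(3):
        for l in range(3):
            dF = np.zeros((3, 3))
            dF[k, l] = h
            out[..., :, :, k, l] = (pk1_stress(F + dF, mat) - P0) / h
    return out


def pk1_tangent_fd(F: np.ndarray, mat, h: float = 1e-6) -> np.ndarray:
    """Material tangent dP/dF by central differences, shape (..., 3,3,3,3)."""
    F = np.asarray(F, dtype=float)
    out = np.empty(F.shape[:-2] + (3, 3, 3, 3))
    for k in range(3):
        for l in range(3):
            dF = np.zeros((3, 3))
            dF[k, l] = h
            Pp = pk1_stress(F + dF, mat)
            Pm = pk1_stress(F - dF, mat)
            out[..., :, :, k, l] = (Pp - Pm) / (2 * h)
    return out


# ---------------------------------------------------------------------------
# boundary conditions / records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryConditions:
    """Micromotion loading: fixed tissue bottom, displaced array top.

    The driven displacement vector is magnitude * (sin th, cos th, 0) with
    ``angle_deg`` measured from the +Y axis in the XY plane.
    """

    displacement_magnitude: float = 10.0  # um
    angle_deg: float = 0.0
    fixed_tag: str = "tissue_bottom"
    driven_tag: str = "array_top"

    @property
    def displacement_vector(self) -> np.ndarray:
        th = np.deg2rad(self.angle_deg)
        return self.displacement_magnitude * np.array(
            [np.sin(th), np.cos(th), 0.0])


@dataclass(frozen=True)
class SolverParams:
    n_load_steps: int = 5
    max_newton_iterations: int = 25
    newton_rtol: float = 1e-8
    newton_atol: float = 1e-6  # pN, scaled Pa-um units
    max_line_search_halvings: int = 5
    # inexact-Newton forcing: the nonlinear residual is always checked
    # exactly, so a loose inner tolerance only adds outer iterations
    krylov_rtol: float = 1e-5
    krylov_maxiter: int = 400
    warm_start_max_residual: float = 1e8  # pN; beyond this, load-step instead
    # reassemble the tangent when the residual contracts slower than this
    # factor per iteration (chord-Newton economy; 1.0 = always reassemble)
    chord_contraction_threshold: float = 0.2
    refresh_iteration_threshold: int = 100
    direct_solve_max_dof: int = 20000
    cheb_degree: int = 2
    verbose: bool = False


@dataclass
class DisplacementField:
    u: np.ndarray  # (n_nodes, 3) um; NaN on nodes outside the solved region
    convergence: list = field(default_factory=list)
    solved_nodes: np.ndarray | None = None  # bool mask
    # intermediate states captured at requested load fractions
    checkpoints: dict = field(default_factory=dict)


@dataclass
class StrainField:
    """Nodal logarithmic (Hencky) strain and von Mises equivalent strain."""

    hencky: np.ndarray  # (n_nodes, 3, 3)
    von_mises: np.ndarray  # (n_nodes,)
    valid: np.ndarray  # bool mask of nodes carrying strain data
    nu_eff: float = 0.5


def von_mises_from_principal(e1, e2, e3, nu_eff: float = 0.5):
    """Equivalent strain from principal strains:
    (1/(1+nu)) * sqrt(0.5 * sum of squared principal differences)."""
    s = 0.5 * ((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2)
    return np.sqrt(s) / (1.0 + nu_eff)


# ---------------------------------------------------------------------------
# quadratic tetrahedra
# ---------------------------------------------------------------------------

# 4-point Gauss rule on the reference tetrahedron (degree 2)
_QA, _QB = 0.5854101966249685, 0.13819660112501052
_QPOINTS = np.array([
    [_QA, _QB, _QB, _QB],
    [_QB, _QA, _QB, _QB],
    [_QB, _QB, _QA, _QB],
    [_QB, _QB, _QB, _QA],
])  # barycentric
_NODAL_BARY = np.vstack([
    np.eye(4),
    [[0.5 if i in e else 0.0 for i in range(4)] for e in
     [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]],
])


def _shape_gradients(bary: np.ndarray, grad_lam: np.ndarray) -> np.ndarray:
    """TET10 shape-function gradients at barycentric points.

    bary: (Q, 4); grad_lam: (E, 4, 3) gradients of the barycentric
    coordinates (constant per straight-sided element).
    Returns (E, Q, 10, 3).
    """
    E = grad_lam.shape[0]
    Q = bary.shape[0]
    G = np.empty((E, Q, 10, 3))
    for q in range(Q):
        lam = bary[q]
        for a in range(4):
            G[:, q, a, :] = (4 * lam[a] - 1) * grad_lam[:, a, :]
        for k, (i, j) in enumerate(TET10_EDGES):
            G[:, q, 4 + k, :] = 4 * (
                lam[i] * grad_lam[:, j, :] + lam[j] * grad_lam[:, i, :])
    return G


class StaticProblem:
    """Assembled static problem on a subset of elements of a TET10 mesh.

    Holds the quadrature data, the sparsity pattern and the Dirichlet sets;
    exposes energy/residual/tangent for the Newton driver and for
    verification tests (residual = gradient of total energy).
    """

    def __init__(self, points: np.ndarray, tets10: np.ndarray,
                 materials: np.ndarray | list, elem_mask: np.ndarray | None = None,
                 n_corner_vertices: int | None = None,
                 midside_parents: np.ndarray | None = None):
        self.n_corner_vertices = n_corner_vertices
        self.midside_parents = midside_parents
        self.points = np.asarray(points, dtype=float)
        tets10 = np.asarray(tets10)
        if elem_mask is not None:
            elem_mask = np.asarray(elem_mask, dtype=bool)
            n_full, n_kept = len(tets10), int(elem_mask.sum())
            tets10 = tets10[elem_mask]
            if isinstance(materials, (list, np.ndarray)):
                if len(materials) == n_full:
                    materials = [m for m, keep in zip(materials, elem_mask)
                                 if keep]
                elif len(materials) != n_kept:
                    raise ValueError(
                        "materials list must match the full or the masked "
                        "element count")
        self.tets = tets10
        self.n_nodes = len(self.points)
        self.ndof = 3 * self.n_nodes
        # group elements by material object for batched kernels
        if not isinstance(materials, (list, np.ndarray)):
            materials = [materials] * len(self.tets)
        self._mat_groups: list[tuple[object, np.ndarray]] = []
        seen: list[object] = []
        mats = list(materials)
        for m in mats:
            if not any(m is s for s in seen):
                seen.append(m)
        for m in seen:
            idx = np.array([i for i, mm in enumerate(mats) if mm is m])
            self._mat_groups.append((m, idx))

        p = self.points
        t = self.tets
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        d3 = p[t[:, 3]] - p[t[:, 0]]
        Dm = np.stack([d1, d2, d3], axis=-1)  # (E,3,3) columns are edges
        vol = np.linalg.det(Dm) / 6.0
        if np.any(vol <= 0):
            raise SolverError("mesh contains non-positive element volumes")
        self.volumes = vol
        Dinv = np.linalg.inv(Dm)  # rows are grad(lam1..3)
        grad_lam = np.empty((len(t), 4, 3))
        grad_lam[:, 1:, :] = Dinv
        grad_lam[:, 0, :] = -Dinv.sum(axis=1)
        self.G = _shape_gradients(_QPOINTS, grad_lam)  # (E,4,10,3)
        self.wq = np.repeat(vol[:, None] / 4.0, 4, axis=1)  # (E,4)
        # dof indices (E, 30): node dofs interleaved (3*n, 3*n+1, 3*n+2)
        self.edofs = (3 * t[:, :, None] + np.arange(3)[None, None, :]
                      ).reshape(len(t), 30).astype(np.int32)
        self._pattern = None
        self._map = None
        self.solved_nodes = np.zeros(self.n_nodes, dtype=bool)
        self.solved_nodes[np.unique(t)] = True

    # -- kernels -----------------------------------------------------------
    def _deformation_gradients(self, u: np.ndarray, G: np.ndarray) -> np.ndarray:
        ue = u[self.tets]  # (E,10,3)
        H = np.einsum("eia,eqib->eqab", ue, G)
        return H + np.eye(3)

    def total_energy(self, u: np.ndarray) -> float:
        F = self._deformation_gradients(u.reshape(self.n_nodes, 3), self.G)
        W = np.empty(F.shape[:2])
        for mat, idx in self._mat_groups:
            W[idx] = _material_energy_F(F[idx], mat)
        return float(np.sum(W * self.wq))

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        """Residual vector (gradient of total energy), shape (ndof,)."""
        F = self._deformation_gradients(u.reshape(self.n_nodes, 3), self.G)
        P = np.empty_like(F)
        for mat, idx in self._mat_groups:
            P[idx] = pk1_stress(F[idx], mat)
        fe = np.einsum("eq,eqik,eqak->eia", self.wq, self.G, P)
        r = np.zeros(self.ndof)
        np.add.at(r, self.edofs.reshape(-1),
                  fe.reshape(len(self.tets), 30).reshape(-1))
        return r

    def _build_pattern(self):
        E = len(self.tets)
        rows = np.repeat(self.edofs, 30, axis=1).ravel()
        cols = np.tile(self.edofs, (1, 30)).ravel()
        pat = sp.coo_matrix(
            (np.ones(len(rows), dtype=np.float32), (rows, cols)),
            shape=(self.ndof, self.ndof)).tocsr()
        pat.sort_indices()
        row_of = np.repeat(np.arange(self.ndof, dtype=np.int64),
                           np.diff(pat.indptr))
        csr_keys = row_of * self.ndof + pat.indices
        del row_of
        ent_keys = rows.astype(np.int64) * self.ndof
        del rows
        ent_keys += cols
        del cols
        self._map = np.searchsorted(csr_keys, ent_keys).astype(np.int32)
        self._pattern = pat
        self._nnz = pat.nnz

    def tangent(self, u: np.ndarray, chunk: int = 6000) -> sp.csr_matrix:
        """Assembled consistent tangent stiffness (finite-difference kernel)."""
        if self._pattern is None:
            self._build_pattern()
        data = np.zeros(self._nnz)
        un = u.reshape(self.n_nodes, 3)
        E = len(self.tets)
        for mat, idx in self._mat_groups:
            for s in range(0, len(idx), chunk):
                sel = idx[s:s + chunk]
                G = self.G[sel]
                ue = un[self.tets[sel]]
                F = np.einsum("eia,eqib->eqab", ue, G) + np.eye(3)
                A = _pk1_tangent_fwd(F, mat)
                wG = self.wq[sel][..., None, None] * G
                # K[e,i,a,j,b] = sum_q wG[e,q,i,k] A[e,q,a,k,b,l] G[e,q,j,l]
                T = np.einsum("eqik,eqakbl->eqaibl", wG, A, optimize=True)
                Ke = np.einsum("eqaibl,eqjl->eiajb", T, G, optimize=True)
                ent = Ke.reshape(len(sel), 30 * 30)
                m = self._map.reshape(E, 900)[sel]
                data += np.bincount(m.ravel(), weights=ent.ravel(),
                                    minlength=self._nnz)
        K = sp.csr_matrix((data, self._pattern.indices.copy(),
                           self._pattern.indptr.copy()),
                          shape=(self.ndof, self.ndof))
        # symmetrize: the energy Hessian is symmetric; forward-difference
        # kernels leave O(h) asymmetry that CG dislikes
        return (K + K.T) * 0.5


class PMultigridPreconditioner:
    """Two-level p-multigrid V(1,1) cycle for the quadratic-tet system.

    The coarse space is the linear (corner-vertex) finite-element subspace:
    midside dofs interpolate as the average of their two edge endpoints, so
    the prolongation P is known exactly from the mesh.  The coarse operator
    A1 = P^T A P is factorized once with sparse LU (it is ~7x smaller than
    the quadratic system, which scipy's SuperLU can handle); high-frequency
    error is damped by a Chebyshev-Jacobi polynomial smoother.  Applied as
    a symmetric preconditioner for CG.
    """

    def __init__(self, A: sp.csc_matrix, free_idx: np.ndarray,
                 n_nodes: int, n_corner: int, parents: np.ndarray,
                 cheb_degree: int = 3, cheb_lower_frac: float = 1 / 20.0):
        self.A = A.tocsr()
        ndof_full = 3 * n_nodes
        rows, cols, vals = [], [], []
        # vertex dofs -> identity
        vtx = np.arange(n_corner)
        for c in range(3):
            rows.append(3 * vtx + c)
            cols.append(3 * vtx + c)
            vals.append(np.ones(n_corner))
        # midside dofs -> average of edge endpoints
        if len(parents):
            mid = n_corner + np.arange(len(parents))
            for c in range(3):
                for k in (0, 1):
                    rows.append(3 * mid + c)
                    cols.append(3 * parents[:, k] + c)
                    vals.append(np.full(len(parents), 0.5))
        P_full = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(ndof_full, 3 * n_corner)).tocsr()
        P = P_full[free_idx]
        # coarse space = free vertex dofs only; the identity block then
        # guarantees full column rank of P (hence SPD A1)
        free_mask = np.zeros(ndof_full, dtype=bool)
        free_mask[free_idx] = True
        keep = np.where(free_mask[: 3 * n_corner])[0]
        P = P.tocsc()[:, keep].tocsr()
        self.P = P
        A1 = (P.T @ (self.A @ P)).tocsc()
        # single-precision coarse factors suffice for a preconditioner and
        # halve the dominant triangular-solve cost; fall back on failure
        try:
            self.coarse_lu = spla.splu(sp.csc_matrix(A1, dtype=np.float32))
            self._coarse_dtype = np.float32
        except RuntimeError:
            self.coarse_lu = spla.splu(A1)
            self._coarse_dtype = np.float64
        d = self.A.diagonal()
        d = np.where(d > 0, d, 1.0)
        self.dinv = 1.0 / d
        self.lmax = self._estimate_lmax()
        self.a = cheb_lower_frac * self.lmax
        self.b = 1.05 * self.lmax
        self.degree = cheb_degree
        # the smoother only shapes the preconditioner; running it in single
        # precision halves the matvec memory traffic
        self.A32 = sp.csr_matrix(self.A, dtype=np.float32)
        self.P32 = sp.csr_matrix(self.P, dtype=np.float32)
        self.dinv32 = self.dinv.astype(np.float32)

    def _estimate_lmax(self, iters: int = 20) -> float:
        rng = np.random.default_rng(12345)
        x = rng.standard_normal(self.A.shape[0])
        lam = 1.0
        for _ in range(iters):
            y = self.dinv * (self.A @ x)
            lam = float(np.linalg.norm(y))
            if lam == 0:
                return 1.0
            x = y / lam
        return lam

    def _smooth(self, b: np.ndarray, x: np.ndarray | None) -> np.ndarray:
        """Chebyshev iteration for D^-1 A with spectrum in [a, b]
        (single precision; preconditioner-grade accuracy)."""
        theta = np.float32(0.5 * (self.b + self.a))
        delta = np.float32(0.5 * (self.b - self.a))
        sigma = theta / delta
        rho = 1.0 / sigma
        if x is None:
            x = np.zeros_like(b)
            r = b
        else:
            r = b - self.A32 @ x
        d = (self.dinv32 * r) / theta
        for k in range(self.degree):
            x = x + d
            r = r - self.A32 @ d
            if k == self.degree - 1:
                break
            rho_new = 1.0 / (2.0 * sigma - rho)
            d = rho_new * rho * d + (2.0 * rho_new / delta) * (self.dinv32 * r)
            rho = rho_new
        return x

    def apply(self, r: np.ndarray) -> np.ndarray:
        r32 = r.astype(np.float32)
        x = self._smooth(r32, None)
        rc = self.P32.T @ (r32 - self.A32 @ x)
        xc = self.coarse_lu.solve(rc.astype(self._coarse_dtype))
        x = x + self.P32 @ xc.astype(np.float32)
        return self._smooth(r32, x).astype(np.float64)

    def as_linear_operator(self) -> spla.LinearOperator:
        return spla.LinearOperator(self.A.shape, matvec=self.apply)


class _LinearSolver:
    """Krylov solves with a frozen p-multigrid preconditioner.

    The preconditioner (coarse LU + smoother data) is built from the first
    tangent and reused across Newton iterations and load steps; it is
    rebuilt only when iteration counts degrade.  Falls back to plain
    sparse LU for small systems or meshes without midside bookkeeping.
    """

    def __init__(self, params: SolverParams, problem: "StaticProblem",
                 free_idx: np.ndarray):
        self.params = params
        self.problem = problem
        self.free_idx = free_idx
        self.pc: PMultigridPreconditioner | None = None
        self.lu = None
        self.iters_last = 0
        small = len(free_idx) <= params.direct_solve_max_dof
        self.use_direct = small or problem.midside_parents is None

    def _build(self, K_ff):
        if self.use_direct:
            self.lu = spla.splu(K_ff.tocsc())
        else:
            self.pc = PMultigridPreconditioner(
                K_ff, self.free_idx, self.problem.n_nodes,
                self.problem.n_corner_vertices, self.problem.midside_parents,
                cheb_degree=self.params.cheb_degree)

    def solve(self, K_ff, b: np.ndarray) -> np.ndarray:
        p = self.params
        if self.use_direct:
            if self.lu is None:
                self._build(K_ff)
            x = self.lu.solve(b)
            # refresh if the frozen factorization has drifted too far
            res = np.linalg.norm(b - K_ff @ x)
            if res > 1e-6 * max(np.linalg.norm(b), 1e-30):
                self._build(K_ff)
                x = self.lu.solve(b)
            return x
        if self.pc is None:
            self._build(K_ff)
        n_it = 0

        def cb(_):
            nonlocal n_it
            n_it += 1

        M = spla.LinearOperator(K_ff.shape, matvec=self.pc.apply)
        x, info = spla.cg(K_ff, b, M=M, rtol=p.krylov_rtol, atol=0.0,
                          maxiter=p.krylov_maxiter, callback=cb)
        if info != 0:
            # rebuild on the current tangent and retry once; a short GMRES
            # is the last resort (tolerates slight indefiniteness) -- fail
            # fast so the Newton driver can bisect the load step instead
            self._build(K_ff)
            M = spla.LinearOperator(K_ff.shape, matvec=self.pc.apply)
            x, info = spla.cg(K_ff, b, M=M, rtol=p.krylov_rtol, atol=0.0,
                              maxiter=p.krylov_maxiter // 2, callback=cb)
            if info != 0:
                x, info = spla.gmres(K_ff, b, M=M, rtol=p.krylov_rtol,
                                     atol=0.0, restart=40, maxiter=3)
                if info != 0:
                    raise SolverError("linear solver failed to converge")
        elif n_it > p.refresh_iteration_threshold:
            self._build(K_ff)
        self.iters_last = n_it
        return x


def _newton_solve(problem: StaticProblem, dirichlet_dofs: np.ndarray,
                  dirichlet_values: np.ndarray, params: SolverParams,
                  checkpoints: list | None = None,
                  initial_guess: np.ndarray | None = None
                  ) -> tuple[np.ndarray, list, dict]:
    """Load-stepped Newton with a consistent linear predictor.

    Each boundary-condition increment is introduced through the linearized
    system K_ff du = -(r_f + K_fc dg) so the interior responds in the same
    update as the prescribed jump (a naive jump would invert the fine tip
    elements).  Steps that fail to converge are bisected adaptively.
    """
    ndof = problem.ndof
    free = np.ones(ndof, dtype=bool)
    free[dirichlet_dofs] = False
    free &= np.repeat(problem.solved_nodes, 3)
    free_idx = np.where(free)[0]
    con_idx = dirichlet_dofs
    u = np.zeros(ndof)
    history: list[dict] = []
    lin = _LinearSolver(params, problem, free_idx)

    def residual_norm(uvec):
        return float(np.linalg.norm(problem.internal_force(uvec)[free_idx]))

    # the assembled tangent is reused across iterations within a load step
    # (chord Newton): CG with the p-MG preconditioner makes extra chord
    # iterations far cheaper than reassembling the finite-difference kernel
    state = {"K_ff": None}

    def reassemble(uvec):
        K = problem.tangent(uvec)
        state["K_ff"] = K[free_idx][:, free_idx].tocsc()
        return K

    def newton_at_fixed_bc(u0, ref_norm, step_label):
        """Iterate to equilibrium at the current Dirichlet values."""
        uc = u0
        prev_norm = None
        for it in range(params.max_newton_iterations):
            r = problem.internal_force(uc)
            rf = r[free_idx]
            rnorm = float(np.linalg.norm(rf))
            history.append({"step": step_label, "iter": it, "residual": rnorm})
            if params.verbose:
                print(f"  load {step_label:.3f} it {it}: |r| = {rnorm:.3e}")
            tol = max(params.newton_atol, params.newton_rtol * ref_norm)
            if rnorm <= tol:
                return uc
            slow = (prev_norm is not None
                    and rnorm > params.chord_contraction_threshold * prev_norm)
            if slow:
                reassemble(uc)
            du = lin.solve(state["K_ff"], -rf)
            alpha, accepted = 1.0, False
            for _ in range(params.max_line_search_halvings + 1):
                u_try = uc.copy()
                u_try[free_idx] += alpha * du
                try:
                    new_norm = residual_norm(u_try)
                except SolverError:
                    new_norm = np.inf
                if new_norm < rnorm:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                raise SolverError("line search failed")
            uc = u_try
            prev_norm = rnorm
        raise SolverError("max Newton iterations reached")

    if initial_guess is not None:
        # warm start (e.g. a coarse-solution interpolant): apply the full
        # boundary data at once and iterate from the guess; fall back to
        # load stepping if the guess is outside the convergence basin
        try:
            u = initial_guess.copy()
            u[con_idx] = dirichlet_values
            r0 = problem.internal_force(u)
            res0 = float(np.linalg.norm(r0[free_idx]))
            if res0 > params.warm_start_max_residual:
                raise SolverError("warm-start residual out of range")
            # tolerance scales with the load (reaction forces), not with
            # the possibly tiny residual of a good guess
            load_scale = float(np.linalg.norm(r0[con_idx]))
            ref = max(load_scale, res0, params.newton_atol)
            reassemble(u)
            u = newton_at_fixed_bc(u, ref, 1.0)
            return u, history, {}
        except SolverError:
            u = np.zeros(ndof)
            state["K_ff"] = None
            if params.verbose:
                print("  warm start failed; falling back to load stepping")

    applied = 0.0
    frac = 1.0 / params.n_load_steps
    min_frac = frac / 64.0
    cps = sorted(c for c in (checkpoints or []) if 0.0 < c <= 1.0)
    captured: dict[float, np.ndarray] = {}
    while applied < 1.0 - 1e-12:
        step = min(frac, 1.0 - applied)
        nxt = next((c for c in cps if c > applied + 1e-12), None)
        if nxt is not None:
            step = min(step, nxt - applied)
        dg = step * dirichlet_values
        # consistent predictor for the BC increment
        r = problem.internal_force(u)
        K = reassemble(u)
        K_fc = K[free_idx][:, con_idx]
        du = lin.solve(state["K_ff"], -(r[free_idx] + K_fc @ dg))
        u_try = u.copy()
        u_try[con_idx] += dg
        u_try[free_idx] += du
        try:
            r_try = problem.internal_force(u_try)
            # reference combines the predictor residual with the reaction
            # (load) scale so stiff inclusions do not push the tolerance
            # below the attainable precision floor
            ref = max(float(np.linalg.norm(r_try[free_idx])),
                      1e-2 * float(np.linalg.norm(r_try[con_idx])),
                      params.newton_atol)
            u = newton_at_fixed_bc(u_try, ref, applied + step)
            applied += step
            for c in cps:
                if abs(applied - c) < 1e-9 and c not in captured:
                    captured[c] = u.copy()
            frac = min(frac * 2.0, 2.0 / params.n_load_steps)
        except SolverError:
            frac = step / 2.0
            if frac < min_frac:
                raise SolverError(
                    f"load stepping stalled at {applied:.3f} of full load")
            if params.verbose:
                print(f"  bisecting load step to {frac:.4f}")
    return u, history, captured


# ---------------------------------------------------------------------------
# high-level solve on a tagged mesh
# ---------------------------------------------------------------------------

def _face_nodes(mesh: Mesh, tag: str) -> np.ndarray:
    """All TET10 nodes lying on the tagged corner-vertex faces."""
    faces = mesh.faces[tag]
    corner = np.unique(faces)
    pts = mesh.points
    # midside nodes are recovered geometrically; exact for the axis-aligned
    # tagged faces used here
    if tag == "tissue_bottom":
        z = pts[:, 2]
        return np.where(np.abs(z - z.min()) < 1e-6 * (z.max() - z.min() + 1)
                        )[0]
    if tag == "array_top":
        z = pts[:, 2]
        return np.where(np.abs(z - z.max()) < 1e-6 * (z.max() - z.min() + 1)
                        )[0]
    return corner


def solve_static(mesh: Mesh, materials: dict, bc: BoundaryConditions,
                 model: SolidModel | None = None, mode: str = "rigid",
                 params: SolverParams | None = None,
                 checkpoints: list | None = None,
                 initial_guess: np.ndarray | None = None
                 ) -> DisplacementField:
    """Solve the micromotion BVP on a tagged array+tissue mesh.

    ``materials`` maps region names to materials, e.g. ``{"tissue":
    OgdenMaterial(), "array": ElasticMaterial()}``.  In ``rigid`` mode the
    array elements are dropped and every node bonded to the array carries
    the full driven displacement (the silicon is ~8 orders of magnitude
    stiffer than tissue); in ``elastic`` mode the silicon region is solved
    with its own material and only the top face of the base is driven.
    """
    params = params or SolverParams()
    if mode not in ("rigid", "elastic"):
        raise ValueError("mode must be 'rigid' or 'elastic'")
    tissue_mat = materials["tissue"]
    if mode == "rigid":
        elem_mask = mesh.region == REGION_TISSUE
        elem_mats = [tissue_mat] * int(elem_mask.sum())
        prob = StaticProblem(mesh.points, mesh.tets, elem_mats, elem_mask,
                             n_corner_vertices=mesh.n_corner_vertices,
                             midside_parents=mesh.midside_parents)
        flags = mesh.node_regions()
        driven_nodes = np.where(flags & 2)[0]
        if model is not None:
            extra = np.where(
                model.shank_lateral_distance(mesh.points) <= 1e-9)[0]
            driven_nodes = np.union1d(driven_nodes, extra)
    else:
        mats = [materials["array"] if r == REGION_ARRAY else tissue_mat
                for r in mesh.region]
        prob = StaticProblem(mesh.points, mesh.tets, mats, None,
                             n_corner_vertices=mesh.n_corner_vertices,
                             midside_parents=mesh.midside_parents)
        driven_nodes = _face_nodes(mesh, bc.driven_tag)
    fixed_nodes = _face_nodes(mesh, bc.fixed_tag)
    driven_nodes = np.setdiff1d(driven_nodes, fixed_nodes)
    vec = bc.displacement_vector
    dofs = np.concatenate([
        (3 * fixed_nodes[:, None] + np.arange(3)).ravel(),
        (3 * driven_nodes[:, None] + np.arange(3)).ravel(),
    ])
    vals = np.concatenate([
        np.zeros(3 * len(fixed_nodes)),
        np.tile(vec, len(driven_nodes)),
    ])
    guess = None
    if initial_guess is not None:
        guess = np.nan_to_num(np.asarray(initial_guess, dtype=float)).ravel()
    u, hist, captured = _newton_solve(prob, dofs, vals, params,
                                      checkpoints=checkpoints,
                                      initial_guess=guess)

    def finalize(uvec, frac=1.0):
        un = uvec.reshape(-1, 3).copy()
        un = np.where(prob.solved_nodes[:, None], un, np.nan)
        # driven nodes always carry their prescribed value (even if only
        # part of the array region was meshed)
        un[driven_nodes] = frac * vec
        un[fixed_nodes] = 0.0
        return un

    cps = {f: finalize(uc, f) for f, uc in captured.items()}
    return DisplacementField(u=finalize(u), convergence=hist,
                             solved_nodes=prob.solved_nodes,
                             checkpoints=cps)


def strain_from_displacement(mesh: Mesh, disp: DisplacementField,
                             elem_mask: np.ndarray | None = None,
                             nu_eff: float = 0.5) -> StrainField:
    """Nodal Hencky strain tensors and von Mises equivalent strain.

    F is evaluated at the 10 nodes of every (solved) element and
    volume-weighted averaged across elements sharing each node; the
    logarithmic strain follows from the polar decomposition
    (eps = 1/2 log C in the principal frame of C).
    """
    if elem_mask is None:
        elem_mask = mesh.region == REGION_TISSUE
    prob_pts = mesh.points
    tets = mesh.tets[elem_mask]
    u = np.nan_to_num(disp.u)
    # per-element nodal F via the nodal-point shape gradients
    p = prob_pts
    d1 = p[tets[:, 1]] - p[tets[:, 0]]
    d2 = p[tets[:, 2]] - p[tets[:, 0]]
    d3 = p[tets[:, 3]] - p[tets[:, 0]]
    Dm = np.stack([d1, d2, d3], axis=-1)
    vol = np.linalg.det(Dm) / 6.0
    Dinv = np.linalg.inv(Dm)
    grad_lam = np.empty((len(tets), 4, 3))
    grad_lam[:, 1:, :] = Dinv
    grad_lam[:, 0, :] = -Dinv.sum(axis=1)
    Gn = _shape_gradients(_NODAL_BARY, grad_lam)  # (E,10,10,3)
    ue = u[tets]
    H = np.einsum("eia,enib->enab", ue, Gn)  # (E,10,3,3) at the 10 nodes
    F = H + np.eye(3)
    n = mesh.n_nodes
    acc = np.zeros((n, 3, 3))
    wacc = np.zeros(n)
    w = np.repeat(vol[:, None], 10, axis=1).ravel()
    idx = tets.ravel()
    np.add.at(acc, idx, F.reshape(-1, 3, 3) * w[:, None, None])
    np.add.at(wacc, idx, w)
    valid = wacc > 0
    Fn = np.tile(np.eye(3), (n, 1, 1))
    Fn[valid] = acc[valid] / wacc[valid, None, None]
    C = np.swapaxes(Fn, -1, -2) @ Fn
    lam2, N = np.linalg.eigh(C)
    lam2 = np.maximum(lam2, 1e-300)
    loge = 0.5 * np.log(lam2)
    hencky = np.einsum("...a,...ia,...ja->...ij", loge, N, N)
    vm = von_mises_from_principal(loge[:, 0], loge[:, 1], loge[:, 2], nu_eff)
    vm[~valid] = 0.0
    return StrainField(hencky=hencky, von_mises=vm, valid=valid,
                       nu_eff=nu_eff)


# ---------------------------------------------------------------------------
# case-file export
# ---------------------------------------------------------------------------

def save_case(path, mesh: Mesh, disp: DisplacementField,
              strain: StrainField, config: dict | None = None) -> None:
    """Bundle mesh + solution fields + a config hash into one HDF5 file."""
    import hashlib
    import json

    import h5py

    cfg = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha256(cfg.encode()).hexdigest()
    with h5py.File(path, "w") as f:
        g = f.create_group("mesh")
        g.create_dataset("points", data=mesh.points)
        g.create_dataset("tets", data=mesh.tets)
        g.create_dataset("region", data=mesh.region)
        g.attrs["n_corner_vertices"] = mesh.n_corner_vertices
        if mesh.midside_parents is not None:
            g.create_dataset("midside_parents", data=mesh.midside_parents)
        for tag, faces in mesh.faces.items():
            g.create_dataset(f"faces_{tag}", data=faces)
        s = f.create_group("solution")
        s.create_dataset("displacement", data=disp.u)
        s.create_dataset("von_mises", data=strain.von_mises)
        s.create_dataset("hencky", data=strain.hencky)
        s.create_dataset("valid", data=strain.valid.astype("i1"))
        f.attrs["config_json"] = cfg
        f.attrs["config_sha256"] = digest


def load_case(path) -> tuple[Mesh, DisplacementField, StrainField, dict]:
    """Read a case file written by :func:`save_case`."""
    import json

    import h5py

    with h5py.File(path, "r") as f:
        g = f["mesh"]
        faces = {k.removeprefix("faces_"): g[k][...]
                 for k in g if k.startswith("faces_")}
        mesh = Mesh(points=g["points"][...], tets=g["tets"][...],
                    region=g["region"][...], faces=faces,
                    n_corner_vertices=int(g.attrs["n_corner_vertices"]),
                    midside_parents=(g["midside_parents"][...]
                                     if "midside_parents" in g else None))
        s = f["solution"]
        disp = DisplacementField(u=s["displacement"][...])
        strain = StrainField(hencky=s["hencky"][...],
                             von_mises=s["von_mises"][...],
                             valid=s["valid"][...].astype(bool))
        config = json.loads(f.attrs["config_json"])
    return mesh, disp, strain, config


# ---------------------------------------------------------------------------
# global-local submodeling
# ---------------------------------------------------------------------------

def _tet10_shape_values(lam: np.ndarray) -> np.ndarray:
    """TET10 shape functions at barycentric coordinates lam (..., 4)."""
    N = np.empty(lam.shape[:-1] + (10,))
    for a in range(4):
        N[..., a] = lam[..., a] * (2 * lam[..., a] - 1)
    for k, (i, j) in enumerate(TET10_EDGES):
        N[..., 4 + k] = 4 * lam[..., i] * lam[..., j]
    return N


def interpolate_displacement(mesh: Mesh, u: np.ndarray, pts: np.ndarray,
                             elem_mask: np.ndarray | None = None,
                             n_candidates: int = 48) -> np.ndarray:
    """Evaluate the quadratic displacement field at arbitrary points.

    Locates each point by checking barycentric coordinates against nearby
    element candidates (KD-tree on element centroids); falls back to the
    least-violating candidate for points marginally outside the solved
    region (e.g. on the staircase interface).
    """
    from scipy.spatial import cKDTree

    if elem_mask is None:
        elem_mask = np.ones(mesh.n_elements, dtype=bool)
    tets = mesh.tets[elem_mask]
    p = mesh.points
    corners = tets[:, :4]
    X0 = p[corners[:, 0]]
    D = np.stack([p[corners[:, 1]] - X0, p[corners[:, 2]] - X0,
                  p[corners[:, 3]] - X0], axis=-1)
    Dinv = np.linalg.inv(D)
    cent = p[corners].mean(axis=1)
    tree = cKDTree(cent)
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    un = np.nan_to_num(np.asarray(u, dtype=float))
    k = min(n_candidates, len(cent))
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand).reshape(len(pts), k)
    # barycentric coordinates of every point in each candidate element
    diff = pts[:, None, :] - X0[cand]  # (P, k, 3)
    xi = np.einsum("pkij,pkj->pki", Dinv[cand], diff)
    lam = np.concatenate([1 - xi.sum(axis=2, keepdims=True), xi], axis=2)
    best = np.argmax(lam.min(axis=2), axis=1)  # least-violating candidate
    rows = np.arange(len(pts))
    lam_b = np.clip(lam[rows, best], 0.0, 1.0)
    lam_b /= lam_b.sum(axis=1, keepdims=True)
    N = _tet10_shape_values(lam_b)  # (P, 10)
    return np.einsum("pn,pnc->pc", N, un[tets[cand[rows, best]]])


def _relax_guess_near_tip(mesh_l: Mesh, prob: "StaticProblem",
                          interp: np.ndarray, driven: np.ndarray, tip,
                          radius: float = 30.0, passes: int = 30) -> None:
    """Laplacian-smooth the warm-start guess near the tip (in place)."""
    pts = mesh_l.points
    d = np.linalg.norm(pts - np.asarray(tip, dtype=float), axis=1)
    n_c = mesh_l.n_corner_vertices
    free = (d < radius) & ~driven & prob.solved_nodes
    free_c = free.copy()
    free_c[n_c:] = False
    if not np.any(free_c):
        return
    # corner-vertex adjacency from the solved elements' edges
    t4 = prob.tets[:, :4]
    pairs = np.concatenate([np.sort(t4[:, (i, j)], axis=1)
                            for i, j in ((0, 1), (0, 2), (0, 3),
                                         (1, 2), (1, 3), (2, 3))])
    pairs = np.unique(pairs, axis=0)
    a, b = pairs[:, 0], pairs[:, 1]
    deg = np.zeros(len(pts))
    np.add.at(deg, a, 1.0)
    np.add.at(deg, b, 1.0)
    for _ in range(passes):
        acc = np.zeros_like(interp)
        np.add.at(acc, a, interp[b])
        np.add.at(acc, b, interp[a])
        avg = acc / np.maximum(deg, 1.0)[:, None]
        interp[free_c] = avg[free_c]
    # midside nodes follow their parent vertices
    parents = mesh_l.midside_parents
    if parents is not None:
        mid = n_c + np.arange(len(parents))
        upd = free[mid]
        interp[mid[upd]] = 0.5 * (interp[parents[upd, 0]]
                                  + interp[parents[upd, 1]])


def solve_submodel(model: SolidModel, global_mesh: Mesh,
                   global_u: np.ndarray, tip, bc: BoundaryConditions,
                   fine_spec: MeshSpec, half_width: float = 90.0,
                   tissue_material: OgdenMaterial | None = None,
                   params: SolverParams | None = None,
                   warm_start: bool = False,
                   guess_mesh: Mesh | None = None,
                   guess_u: np.ndarray | None = None
                   ) -> tuple[Mesh, DisplacementField, StrainField]:
    """Fine-mesh solve around one tip driven by the coarse global solution.

    The submodel box boundary carries Dirichlet data interpolated from the
    global displacement field; nodes bonded to the (rigid) array carry the
    full driven displacement.  Both are ramped together by the load
    stepping.
    """
    from .meshing import generate_local_mesh

    params = params or SolverParams(n_load_steps=3)
    mat = tissue_material or OgdenMaterial()
    mesh_l = generate_local_mesh(model, tip, half_width, fine_spec)
    elem_mask = mesh_l.region == REGION_TISSUE
    prob = StaticProblem(mesh_l.points, mesh_l.tets, mat, elem_mask,
                         n_corner_vertices=mesh_l.n_corner_vertices,
                         midside_parents=mesh_l.midside_parents)
    flags = mesh_l.node_regions()
    driven = (flags & 2) > 0
    driven |= model.shank_lateral_distance(mesh_l.points) <= 1e-9
    lo, hi = mesh_l.provenance["bounds"]
    ptsl = mesh_l.points
    eps = 1e-6 * half_width
    outer = np.zeros(len(ptsl), dtype=bool)
    for k in range(3):
        outer |= np.abs(ptsl[:, k] - lo[k]) < eps
        outer |= np.abs(ptsl[:, k] - hi[k]) < eps
    outer &= ~driven
    outer &= prob.solved_nodes
    vec = bc.displacement_vector
    g_tissue = global_mesh.region == REGION_TISSUE
    # interpolate the coarse global field over the whole submodel: boundary
    # values become Dirichlet data, interior values the Newton warm start
    interp = np.zeros_like(ptsl)
    query = prob.solved_nodes | driven
    interp[query] = interpolate_displacement(
        global_mesh, global_u, ptsl[query], elem_mask=g_tissue)
    interp[driven] = vec
    if guess_mesh is not None and guess_u is not None:
        # warm start from a previously solved (finer-study) local field:
        # unlike the coarse global interpolant this resolves the tip
        # boundary layer, so full-load Newton usually converges directly
        warm_start = True
        g_mask = guess_mesh.region == REGION_TISSUE
        interp2 = interp.copy()
        interp2[query] = interpolate_displacement(
            guess_mesh, guess_u, ptsl[query], elem_mask=g_mask)
        interp2[driven] = vec
        interp = interp2
    elif warm_start:
        # near the tip the coarse interpolant cannot represent the boundary
        # layer and may invert fine elements; relax it toward a smooth
        # field (Jacobi passes on the corner-vertex graph, BC data pinned)
        _relax_guess_near_tip(mesh_l, prob, interp, driven, tip)
    d_idx = np.where(driven)[0]
    o_idx = np.where(outer)[0]
    dofs = np.concatenate([
        (3 * d_idx[:, None] + np.arange(3)).ravel(),
        (3 * o_idx[:, None] + np.arange(3)).ravel()])
    vals = np.concatenate([np.tile(vec, len(d_idx)),
                           interp[o_idx].ravel()])
    u, hist, _ = _newton_solve(
        prob, dofs, vals, params,
        initial_guess=interp.ravel() if warm_start else None)
    un = u.reshape(-1, 3)
    un = np.where(prob.solved_nodes[:, None], un, np.nan)
    un[d_idx] = vec
    disp = DisplacementField(u=un, convergence=hist,
                             solved_nodes=prob.solved_nodes)
    strain = strain_from_displacement(mesh_l, disp, elem_mask=elem_mask)
    return mesh_l, disp, strain


# ---------------------------------------------------------------------------
# study drivers
# ---------------------------------------------------------------------------

@dataclass
class MicromotionResult:
    mesh: Mesh
    model: SolidModel
    layout: object
    displacement: DisplacementField
    strain: StrainField
    electrode_table: object  # pandas DataFrame from strain_roi
    wall_time_s: float = 0.0


def run_micromotion_case(array_spec, tissue_spec, mesh_spec: MeshSpec,
                         bc: BoundaryConditions,
                         mode: str = "rigid",
                         tissue_material: OgdenMaterial | None = None,
                         array_material: ElasticMaterial | None = None,
                         params: SolverParams | None = None,
                         roi_radius: float = 50.0,
                         roi_bin_width: float = 2.5,
                         mesh: Mesh | None = None,
                         connectivity: str = "all",
                         checkpoints: list | None = None) -> MicromotionResult:
    """Build (or reuse) the mesh, solve the BVP and summarize per-electrode
    ROI strain metrics."""
    from .geometry import build_geometry, build_layout
    from .roi import electrode_strain_table

    t0 = time.time()
    model = build_geometry(array_spec, tissue_spec)
    layout = build_layout(model, connectivity)
    if mesh is None:
        from .meshing import generate_mesh
        mesh = generate_mesh(model, mesh_spec)
    materials = {
        "tissue": tissue_material or OgdenMaterial(),
        "array": array_material or ElasticMaterial(),
    }
    disp = solve_static(mesh, materials, bc, model=model, mode=mode,
                        params=params, checkpoints=checkpoints)
    strain = strain_from_displacement(mesh, disp)
    table = electrode_strain_table(
        mesh, strain, layout, radius=roi_radius, bin_width=roi_bin_width)
    return MicromotionResult(mesh=mesh, model=model, layout=layout,
                             displacement=disp, strain=strain,
                             electrode_table=table,
                             wall_time_s=time.time() - t0)


def electrode_table_for_displacement(result: MicromotionResult,
                                     u: np.ndarray,
                                     roi_radius: float = 50.0,
                                     roi_bin_width: float = 2.5):
    """ROI strain table for an alternative displacement state (e.g. a load
    checkpoint of a magnitude sweep) on the same mesh."""
    from .roi import electrode_strain_table

    disp = DisplacementField(u=u, solved_nodes=result.displacement.solved_nodes)
    strain = strain_from_displacement(result.mesh, disp)
    return electrode_strain_table(result.mesh, strain, result.layout,
                                  radius=roi_radius, bin_width=roi_bin_width)


def refine_table_with_submodels(result: "MicromotionResult",
                                fine_spec: MeshSpec,
                                half_width: float = 90.0,
                                params: SolverParams | None = None,
                                roi_radius: float = 50.0,
                                roi_bin_width: float = 2.5,
                                tissue_material: OgdenMaterial | None = None,
                                bc: BoundaryConditions | None = None,
                                displacement: np.ndarray | None = None):
    """Recompute the per-electrode ROI metrics on fine tip submodels.

    Each tip gets a local mesh at ``fine_spec.tip_max_edge`` driven by the
    (coarse) global solution of ``result``; the returned table replaces
    avg_strain / max_strain with the submodel values.
    """
    from .roi import max_strain as roi_max
    from .roi import roi_profile, volume_weighted_average

    bc = bc or BoundaryConditions()
    u_global = result.displacement.u if displacement is None else displacement
    table = result.electrode_table.copy()
    tips = table[["tip_x", "tip_y", "tip_z"]].to_numpy()
    # all tips share one local mesh/problem template up to translation
    # (the submodel box never intersects a neighboring shank at 400 um
    # pitch, and the boxes are interior to the tissue block)
    template = None
    for i, tip in enumerate(tips):
        mesh_l, _, strain_l, template = _solve_submodel_templated(
            result.model, result.mesh, u_global, tip, bc, fine_spec,
            half_width=half_width, tissue_material=tissue_material,
            params=params, template=template)
        prof = roi_profile(mesh_l, strain_l, tip, electrode_id=i,
                           radius=roi_radius, bin_width=roi_bin_width)
        table.loc[table.index[i], "avg_strain"] = \
            volume_weighted_average(prof)
        table.loc[table.index[i], "max_strain"] = \
            roi_max(mesh_l, strain_l, tip, roi_radius)
    return table


def _solve_submodel_templated(model, global_mesh, global_u, tip, bc,
                              fine_spec, half_width, tissue_material,
                              params, template):
    """solve_submodel with mesh/problem reuse across translated tips."""
    from dataclasses import replace as drep

    from .meshing import generate_local_mesh

    params = params or SolverParams(n_load_steps=2)
    mat = tissue_material or OgdenMaterial()
    if template is None:
        mesh_0 = generate_local_mesh(model, tip, half_width, fine_spec)
        elem_mask = mesh_0.region == REGION_TISSUE
        prob = StaticProblem(mesh_0.points, mesh_0.tets, mat, elem_mask,
                             n_corner_vertices=mesh_0.n_corner_vertices,
                             midside_parents=mesh_0.midside_parents)
        flags = mesh_0.node_regions()
        driven = (flags & 2) > 0
        driven |= model.shank_lateral_distance(mesh_0.points) <= 1e-9
        lo, hi = mesh_0.provenance["bounds"]
        eps = 1e-6 * half_width
        outer = np.zeros(mesh_0.n_nodes, dtype=bool)
        for k in range(3):
            outer |= np.abs(mesh_0.points[:, k] - lo[k]) < eps
            outer |= np.abs(mesh_0.points[:, k] - hi[k]) < eps
        outer &= ~driven
        outer &= prob.solved_nodes
        template = {"mesh": mesh_0, "prob": prob, "driven": driven,
                    "outer": outer, "elem_mask": elem_mask,
                    "tip0": np.asarray(tip, dtype=float)}
    t = template
    shift = np.asarray(tip, dtype=float) - t["tip0"]
    mesh_l = drep(t["mesh"], points=t["mesh"].points + shift)
    prob = t["prob"]  # translation-invariant (gradients, volumes, pattern)
    driven, outer = t["driven"], t["outer"]
    vec = bc.displacement_vector
    g_tissue = global_mesh.region == REGION_TISSUE
    o_idx = np.where(outer)[0]
    d_idx = np.where(driven)[0]
    outer_vals = interpolate_displacement(
        global_mesh, global_u, mesh_l.points[o_idx], elem_mask=g_tissue)
    dofs = np.concatenate([
        (3 * d_idx[:, None] + np.arange(3)).ravel(),
        (3 * o_idx[:, None] + np.arange(3)).ravel()])
    vals = np.concatenate([np.tile(vec, len(d_idx)), outer_vals.ravel()])
    # consecutive tips see nearly identical local fields: reuse the last
    # converged state as the warm start (falls back to load stepping)
    guess = t.get("last_u")
    u, hist, _ = _newton_solve(prob, dofs, vals, params,
                               initial_guess=guess)
    t["last_u"] = u.copy()
    un = u.reshape(-1, 3)
    un = np.where(prob.solved_nodes[:, None], un, np.nan)
    un[d_idx] = vec
    disp = DisplacementField(u=un, convergence=hist,
                             solved_nodes=prob.solved_nodes)
    strain = strain_from_displacement(mesh_l, disp,
                                      elem_mask=t["elem_mask"])
    return mesh_l, disp, strain, template


def mesh_convergence_study(array_spec, tissue_spec, edge_sizes,
                           bc: BoundaryConditions,
                           global_mesh_spec: MeshSpec | None = None,
                           fine_base_spec: MeshSpec | None = None,
                           half_width: float = 80.0,
                           params: SolverParams | None = None,
                           roi_radius: float = 50.0,
                           roi_bin_width: float = 2.5):
    """Single-shank refinement sweep: tip edge size -> ROI-average strain.

    One coarse global solve provides the far field; each edge size then
    gets a fine tip submodel on the same boundary data, so the sweep
    isolates the tip discretization error.  Returns a DataFrame with one
    row per edge size (descending) and the relative error against the
    finest mesh.
    """
    import pandas as pd

    sizes = sorted(edge_sizes, reverse=True)
    if len(sizes) < 1:
        raise ValueError("need at least one edge size")
    gspec = global_mesh_spec or MeshSpec(tip_max_edge=12.0,
                                         sphere_of_influence_radius=3.0,
                                         shank_refine_factor=4.0)
    res = run_micromotion_case(array_spec, tissue_spec, gspec, bc,
                               params=params, roi_radius=roi_radius,
                               roi_bin_width=roi_bin_width)
    base = fine_base_spec or replace(gspec, sphere_of_influence_radius=2.5)
    tip = res.model.tips[0]
    rows = []
    from .roi import max_strain as roi_max
    from .roi import roi_profile, volume_weighted_average

    for h in sizes:
        spec = replace(base, tip_max_edge=h)
        t0 = time.time()
        mesh_l, disp_l, strain_l = solve_submodel(
            res.model, res.mesh, res.displacement.u, tip, bc, spec,
            half_width=half_width, params=params)
        prof = roi_profile(mesh_l, strain_l, tip, radius=roi_radius,
                           bin_width=roi_bin_width)
        rows.append({
            "tip_edge_um": h,
            "avg_strain": volume_weighted_average(prof),
            "max_strain": roi_max(mesh_l, strain_l, tip, roi_radius),
            "n_elements": mesh_l.n_elements,
            "wall_time_s": time.time() - t0,
        })
    df = pd.DataFrame(rows)
    finest = df["avg_strain"].iloc[-1]
    df["rel_error_vs_finest"] = np.abs(df["avg_strain"] - finest) / abs(finest)
    return df
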