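"""Small-strain linear-elastic tetrahedral finite-element solver.

Consistent unit system: mm, N, MPa.  Degrees of freedom are nodal
displacements in mm, flattened as ``dof = 3*node + component``.

Elements are isoparametric TET4 (constant strain, 1-point rule) or straight-
edged TET10 (4-point Gauss rule); both use the affine corner geometry, so the
Jacobian is constant per element.  Strain/stress are reported per element as
the average over integration points, in Voigt order
(xx, yy, zz, xy, yz, zx) with *engineering* shear strains.

Dirichlet boundary conditions (optionally inhomogeneous) are applied by
reduction to the free degrees of freedom; the solver is a direct sparse
factorization up to 2e5 free DOF and a Jacobi-preconditioned conjugate
gradient beyond.  Every solve checks the relative residual and global
equilibrium (reactions balance applied loads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshmat import MaterialField, TetMesh, _EDGES10
from .volume import LABEL_NAMES

logger = logging.getLogger(__name__)

DIRECT_SOLVER_MAX_DOF = 200_000
RESIDUAL_TOL = 1e-8
EQUILIBRIUM_TOL = 1e-6

# 4-point Gauss rule on the reference tetrahedron (barycentric, weight 1/4)
_GAUSS_A = 0.585_410_196_624_9685
_GAUSS_B = 0.138_196_601_125_0105
_TET10_GAUSS = np.array(
    [
        [_GAUSS_A, _GAUSS_B, _GAUSS_B, _GAUSS_B],
        [_GAUSS_B, _GAUSS_A, _GAUSS_B, _GAUSS_B],
        [_GAUSS_B, _GAUSS_B, _GAUSS_A, _GAUSS_B],
        [_GAUSS_B, _GAUSS_B, _GAUSS_B, _GAUSS_A],
    ]
)


class SolverError(RuntimeError):
    pass


@dataclass
class LoadCase:
    """Fixed distal node set plus a force distributed over proximal nodes.

    ``force`` is the total force vector in N, split over ``load_nodes``
    either equally or with tributary-area (work-consistent for a uniform
    traction) weights.  ``fixed_values`` optionally prescribes nonzero
    displacements (mm) on the fixed nodes.
    """

    fixed_nodes: np.ndarray
    load_nodes: np.ndarray
    force: tuple[float, float, float] = (0.0, 0.0, 0.0)
    distribution: str = "equal"  # or "consistent"
    fixed_values: np.ndarray | None = None  # (n_fixed, 3) mm
    description: str = ""

    def __post_init__(self) -> None:
        self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=np.int64))
        self.load_nodes = np.unique(np.asarray(self.load_nodes, dtype=np.int64))
        if self.fixed_nodes.size == 0:
            raise ValueError("fixed region must be non-empty")
        if np.intersect1d(self.fixed_nodes, self.load_nodes).size:
            raise ValueError("fixed and load regions must be disjoint")
        force = np.asarray(self.force, dtype=float)
        if force.shape != (3,) or not np.isfinite(force).all():
            raise ValueError("force must be a finite 3-vector")
        self.force = tuple(force)
        if self.load_nodes.size == 0 and np.any(force != 0):
            raise ValueError("nonzero force needs a non-empty load region")
        if self.distribution not in ("equal", "consistent"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.fixed_values is not None:
            self.fixed_values = np.asarray(self.fixed_values, dtype=float)
            if self.fixed_values.shape != (self.fixed_nodes.size, 3):
                raise ValueError("fixed_values must be (n_fixed, 3)")


@dataclass
class FieldSolution:
    """Nodal displacements plus per-element strain/stress fields."""

    displacement: np.ndarray  # (n_nodes, 3) mm
    strain: np.ndarray  # (n_elem, 6) Voigt, engineering shear
    stress: np.ndarray  # (n_elem, 6) MPa
    von_mises: np.ndarray  # (n_elem,) MPa
    diagnostics: dict = field(default_factory=dict)


def nodes_on_plane(mesh: TetMesh, axis: int, value: float, tol: float = 1e-9):
    """Indices of mesh nodes lying on the plane ``coord[axis] == value``."""
    return np.flatnonzero(np.abs(mesh.nodes[:, axis] - value) <= tol)


def isotropic_stiffness(E, nu) -> np.ndarray:
    """6x6 isotropic elasticity matrices (engineering Voigt), batched."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    nu = np.broadcast_to(np.asarray(nu, dtype=float), E.shape)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            C[..., i, j] = lam
        C[..., i, i] = lam + 2 * mu
        C[..., 3 + i, 3 + i] = mu
    return C


def _element_geometry(mesh: TetMesh, sel=slice(None)):
    """Constant per-element Jacobian data: det and barycentric gradients.

    Returns (detJ, G) with detJ = 6 * volume and G[(m), i, :] = grad of
    barycentric coordinate i+1 (i = 0..2).
    """
    x = mesh.nodes[mesh.elements[sel, :4]]
    Emat = x[:, 1:] - x[:, :1]  # rows e_i = x_i - x_0
    detJ = np.linalg.det(Emat)
    bad = np.flatnonzero(detJ <= 0)
    if bad.size:
        raise SolverError(
            f"inverted element {int(bad[0])} (non-positive Jacobian)"
        )
    G = np.linalg.inv(Emat).transpose(0, 2, 1)  # rows = grad lambda_{1..3}
    return detJ, G


def _shape_gradients(mesh: TetMesh, G: np.ndarray):
    """Per-gauss-point shape-function gradients (m, n_nodes_el, 3).

    Yields (weight, dNdx) pairs; the affine geometry makes the Jacobian
    constant, so only the reference gradients vary between points.
    """
    if mesh.order == 1:
        dNdl = np.array(
            [[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        )
        yield 1.0, np.einsum("nk,mkj->mnj", dNdl, G)
        return
    for lam in _TET10_GAUSS:
        dNdl = np.zeros((10, 3))
        dNdl[0, :] = -(4 * lam[0] - 1)
        for i in range(1, 4):
            dNdl[i, i - 1] = 4 * lam[i] - 1
        for e, (a, b) in enumerate(_EDGES10):
            for k in range(3):
                da = -1.0 if a == 0 else (1.0 if a == k + 1 else 0.0)
                db = -1.0 if b == 0 else (1.0 if b == k + 1 else 0.0)
                dNdl[4 + e, k] = 4 * (lam[b] * da + lam[a] * db)
        yield 0.25, np.einsum("nk,mkj->mnj", dNdl, G)


def _b_matrix(dNdx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (m, 6, 3*n) from shape gradients."""
    m, n, _ = dNdx.shape
    B = np.zeros((m, 6, 3 * n))
    gx, gy, gz = dNdx[..., 0], dNdx[..., 1], dNdx[..., 2]
    cols = 3 * np.arange(n)
    B[:, 0, cols + 0] = gx
    B[:, 1, cols + 1] = gy
    B[:, 2, cols + 2] = gz
    B[:, 3, cols + 0] = gy
    B[:, 3, cols + 1] = gx
    B[:, 4, cols + 1] = gz
    B[:, 4, cols + 2] = gy
    B[:, 5, cols + 0] = gz
    B[:, 5, cols + 2] = gx
    return B


def assemble_stiffness(mesh: TetMesh, mats: MaterialField) -> sp.csr_matrix:
    """Global stiffness matrix (symmetric positive semi-definite).

    1-point integration for TET4, 4-point for TET10; exact for the affine
    elements used here.  Raises on inverted elements, naming the first.
    """
    if mats.young_modulus.shape[0] != mesh.n_elements:
        raise ValueError("materials do not match mesh element count")
    ndof = 3 * mesh.n_nodes
    npe = 4 if mesh.order == 1 else 10
    d = 3 * npe
    chunk = max(1, int(8e7 // (d * d * 8)))
    rows, cols, vals = [], [], []
    for start in range(0, mesh.n_elements, chunk):
        sel = slice(start, min(start + chunk, mesh.n_elements))
        detJ, G = _element_geometry(mesh, sel)
        C = isotropic_stiffness(
            mats.young_modulus[sel], mats.poisson_ratio[sel]
        )
        sub = TetMesh(
            mesh.nodes, mesh.elements[sel], mesh.element_part[sel], mesh.order
        )
        Ke = np.zeros((detJ.shape[0], d, d))
        for w, dNdx in _shape_gradients(sub, G):
            B = _b_matrix(dNdx)
            CB = np.einsum("mij,mja->mia", C, B)
            Ke += (w / 6.0) * detJ[:, None, None] * np.einsum(
                "mia,mib->mab", B, CB
            )
        edof = (3 * mesh.elements[sel, :, None]
                + np.arange(3)[None, None, :]).reshape(-1, d)
        rows.append(np.repeat(edof, d, axis=1).ravel())
        cols.append(np.tile(edof, (1, d)).ravel())
        vals.append(Ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()
    return K


def _boundary_faces(mesh: TetMesh):
    """Corner-node triples of faces that belong to exactly one element.

    Returns (faces, elem_idx, local_face) with faces in element-local
    orientation.
    """
    local_faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    corners = mesh.elements[:, :4]
    faces = corners[:, local_faces]  # (m, 4, 3)
    flat = faces.reshape(-1, 3)
    key = np.sort(flat, axis=1)
    _, inv, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    on_boundary = counts[inv] == 1
    elem_idx = np.repeat(np.arange(mesh.n_elements), 4)[on_boundary]
    local_idx = np.tile(np.arange(4), mesh.n_elements)[on_boundary]
    return flat[on_boundary], elem_idx, local_idx


def surface_load_weights(mesh: TetMesh, load_nodes: np.ndarray) -> np.ndarray:
    """Work-consistent nodal weights for a uniform traction on the surface
    spanned by ``load_nodes``.

    Boundary triangles whose corner nodes all belong to the load set
    contribute area/3 to each corner (TET4) or area/3 to each midside node
    with zero corner share (TET10, the classic quadratic-triangle rule).
    Weights are normalized to sum to 1.
    """
    in_set = np.zeros(mesh.n_nodes, dtype=bool)
    in_set[load_nodes] = True
    faces, elem_idx, _ = _boundary_faces(mesh)
    keep = in_set[faces].all(axis=1)
    faces = faces[keep]
    elem_idx = elem_idx[keep]
    if faces.shape[0] == 0:
        raise ValueError("no boundary faces span the load region")
    p = mesh.nodes[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    w = np.zeros(mesh.n_nodes)
    if mesh.order == 1:
        np.add.at(w, faces.ravel(), np.repeat(areas / 3.0, 3))
    else:
        pair_to_edge = {tuple(sorted(e)): i for i, e in enumerate(_EDGES10)}
        elems = mesh.elements[elem_idx]
        corners = elems[:, :4]
        for fi in range(faces.shape[0]):
            local = [int(np.flatnonzero(corners[fi] == g)[0]) for g in faces[fi]]
            for a, b in ((0, 1), (1, 2), (0, 2)):
                e = pair_to_edge[tuple(sorted((local[a], local[b])))]
                w[elems[fi, 4 + e]] += areas[fi] / 3.0
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate load surface")
    return w / total


def build_load_vector(mesh: TetMesh, loadcase: LoadCase) -> np.ndarray:
    f = np.zeros((mesh.n_nodes, 3))
    force = np.asarray(loadcase.force)
    if loadcase.load_nodes.size and np.any(force != 0):
        if loadcase.distribution == "equal":
            f[loadcase.load_nodes] = force / loadcase.load_nodes.size
        else:
            w = surface_load_weights(mesh, loadcase.load_nodes)
            f += w[:, None] * force[None, :]
    return f.ravel()


def element_strains(mesh: TetMesh, u: np.ndarray) -> np.ndarray:
    """Per-element strain (Voigt, engineering shear), integration-point
    average."""
    ue = u.reshape(-1, 3)[mesh.elements].reshape(mesh.n_elements, -1)
    _, G = _element_geometry(mesh)
    eps = np.zeros((mesh.n_elements, 6))
    wsum = 0.0
    for w, dNdx in _shape_gradients(mesh, G):
        B = _b_matrix(dNdx)
        eps += w * np.einsum("mij,mj->mi", B, ue)
        wsum += w
    return eps / wsum


def von_mises(sigma) -> np.ndarray | float:
    """Von Mises equivalent stress, sqrt(3 J2) of the stress deviator.

    Accepts Voigt vectors (..., 6) in (xx, yy, zz, xy, yz, zx) order or full
    (..., 3, 3) tensors.
    """
    s = np.asarray(sigma, dtype=float)
    if s.shape[-2:] == (3, 3):
        sx, sy, sz = s[..., 0, 0], s[..., 1, 1], s[..., 2, 2]
        txy, tyz, tzx = s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]
    elif s.shape[-1] == 6:
        sx, sy, sz, txy, tyz, tzx = (s[..., i] for i in range(6))
    else:
        raise ValueError("stress must be (..., 6) Voigt or (..., 3, 3)")
    out = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
    return float(out) if out.ndim == 0 else out


def solve(
    K: sp.spmatrix,
    loadcase: LoadCase,
    mesh: TetMesh,
    mats: MaterialField,
) -> FieldSolution:
    """Solve the constrained linear system and recover element fields.

    Raises :class:`SolverError` on singular systems, non-converged iterative
    solves, or equilibrium violation beyond 1e-6 relative.
    """
    ndof = 3 * mesh.n_nodes
    K = K.tocsr()
    f = build_load_vector(mesh, loadcase)

    fixed_dofs = (3 * loadcase.fixed_nodes[:, None] + np.arange(3)).ravel()
    u = np.zeros(ndof)
    if loadcase.fixed_values is not None:
        u[fixed_dofs] = loadcase.fixed_values.ravel()
    free = np.ones(ndof, dtype=bool)
    free[fixed_dofs] = False
    free_idx = np.flatnonzero(free)

    Kff = K[free_idx][:, free_idx]
    rhs = f[free_idx] - K[free_idx][:, fixed_dofs] @ u[fixed_dofs]

    n_free = free_idx.size
    diag = Kff.diagonal()
    if n_free and np.any(diag <= 0):
        raise SolverError(
            "singular system: zero diagonal stiffness on free DOFs "
            "(insufficient constraints or disconnected nodes)"
        )
    iterations = 0
    if n_free == 0:
        uf = np.zeros(0)
        method = "none"
    elif n_free <= DIRECT_SOLVER_MAX_DOF:
        try:
            uf = spla.spsolve(Kff.tocsc(), rhs)
        except RuntimeError as exc:  # pragma: no cover - factorization failure
            raise SolverError(f"direct solve failed: {exc}") from exc
        if not np.all(np.isfinite(uf)):
            raise SolverError("singular system: direct solve returned NaN/inf")
        method = "direct"
    else:
        M = spla.LinearOperator(
            Kff.shape, matvec=lambda x: x / diag
        )
        it_count = [0]

        def _cb(_):
            it_count[0] += 1

        uf, info = spla.cg(
            Kff, rhs, rtol=RESIDUAL_TOL, atol=0.0, M=M, maxiter=20 * n_free,
            callback=_cb,
        )
        if info != 0:
            raise SolverError(f"conjugate gradient did not converge ({info})")
        iterations = it_count[0]
        method = "cg"
    u[free_idx] = uf

    rhs_norm = np.linalg.norm(rhs) if n_free else 0.0
    residual = (
        np.linalg.norm(Kff @ uf - rhs) / rhs_norm if rhs_norm > 0 else 0.0
    )
    if residual > RESIDUAL_TOL * 10:
        raise SolverError(f"relative residual {residual:.2e} too large")

    # reactions and global equilibrium
    r = K @ u - f
    reactions = r[fixed_dofs].reshape(-1, 3)
    applied = f.reshape(-1, 3).sum(axis=0)
    balance = reactions.sum(axis=0) + applied
    scale = max(
        np.linalg.norm(applied),
        float(np.abs(reactions).sum()),
        1e-12,
    )
    equilibrium_rel = float(np.linalg.norm(balance) / scale)
    if scale > 1e-12 and equilibrium_rel > EQUILIBRIUM_TOL:
        raise SolverError(
            f"global equilibrium violated: relative imbalance "
            f"{equilibrium_rel:.2e}"
        )

    eps = element_strains(mesh, u)
    C = isotropic_stiffness(mats.young_modulus, mats.poisson_ratio)
    sig = np.einsum("mij,mj->mi", C, eps)
    vm = von_mises(sig)

    return FieldSolution(
        displacement=u.reshape(-1, 3),
        strain=eps,
        stress=sig,
        von_mises=vm,
        diagnostics={
            "method": method,
            "iterations": iterations,
            "residual": float(residual),
            "equilibrium_rel": equilibrium_rel,
            "n_free_dof": int(n_free),
            "reaction_total": reactions.sum(axis=0).tolist(),
        },
    )


def max_von_mises_by_part(sol: FieldSolution, mesh: TetMesh) -> dict:
    """Per-part maximum von Mises stress and the element attaining it.

    Deterministic tie-break: lowest element id.  Empty parts are absent from
    the map (and logged).
    """
    out = {}
    for part in np.unique(mesh.element_part):
        sel = np.flatnonzero(mesh.element_part == part)
        if sel.size == 0:  # pragma: no cover - unique() precludes this
            logger.info("part %s has no elements", part)
            continue
        vm = sol.von_mises[sel]
        k = int(np.argmax(vm))
        name = LABEL_NAMES.get(int(part), str(int(part)))
        out[name] = (float(vm[k]), int(sel[k]))
    return out
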