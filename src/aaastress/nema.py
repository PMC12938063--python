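"""Inverse membrane equilibrium wall-stress estimation (NEMA).

A pressurized thin-walled vessel imaged in its deformed configuration is
nearly statically determinate: the in-plane Cauchy stress follows from
equilibrium and the applied load alone, with no constitutive model.  On a
triangulated surface with uniform thickness ``h`` and internal pressure
``p`` the pointwise membrane equilibrium is

    (1/sqrt(g)) (sqrt(g) h sigma^{ab} g_a),_b + p n = 0 ,

with ``g_a`` the covariant tangent basis, ``g`` the determinant of the
metric tensor g_ab = g_a . g_b, ``sigma^{ab}`` the contravariant in-plane
Cauchy stress components and ``n`` the outward unit normal.

Discretization
--------------
Linear shape functions on each triangle; stress unknowns are *nodal* — three
components per vertex, stored in a per-vertex orthonormal tangent frame so
that nodal values shared between elements are well defined — and rotated
into each element's covariant basis during assembly.  Galerkin weighting
yields three force-balance equations per free (non-boundary) vertex:

    sum_e  h sqrt(g) (dN_a/dxi_b) g_a_comp sigma^{ab}  =  p A_e / 3 n_e

Boundary-ring vertices ("fixed proximal and distal ends") carry no balance
equations; their reactions absorb the imbalance.  The resulting linear
system is solved in the minimum-Frobenius-norm least-squares sense (tiny
Tikhonov damping on the damped normal equations), which resolves the
statically indeterminate axial mode of an open tube to zero — the membrane
solution with no applied end load.

Element centroid stresses are the average of the vertex values, and
principal stresses are the eigenvalues of the physical stress tensor in each
element's tangent plane.  Stresses are reported in N/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import SurfaceMesh, element_geometry

PA_PER_MMHG = 133.322
NCM2_PER_PA = 1e-4  # 1 Pa = 1 N/m^2 = 1e-4 N/cm^2


def convert_pressure(p_mmHg: float) -> float:
    """Convert pressure from mmHg to N/cm^2 (133.322 Pa per mmHg)."""
    if p_mmHg < 0:
        raise ValueError(f"pressure must be non-negative, got {p_mmHg}")
    return p_mmHg * PA_PER_MMHG * NCM2_PER_PA


@dataclass(frozen=True)
class LoadCase:
    """Uniform load on the wall: intraluminal pressure and wall thickness."""

    pressure_mmHg: float = 93.3
    thickness_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.pressure_mmHg < 0:
            raise ValueError("pressure must be non-negative")
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")

    @property
    def pressure_internal(self) -> float:
        """Pressure in N/cm^2."""
        return convert_pressure(self.pressure_mmHg)

    @property
    def thickness_h(self) -> float:
        """Wall thickness in cm."""
        return self.thickness_mm / 10.0


@dataclass(frozen=True)
class MembraneElement:
    """Local differential geometry of one triangle.

    The covariant basis vectors are the two edge vectors from vertex 0 (the
    linear shape-function map from the reference triangle), so
    g_det = (2 * area)^2.
    """

    g1: np.ndarray
    g2: np.ndarray
    metric: np.ndarray  # 2x2 g_ab
    g_det: float
    normal: np.ndarray
    centroid: np.ndarray
    area: float


def element_basis(mesh: SurfaceMesh, index: int) -> MembraneElement:
    """Covariant basis, metric, normal and centroid of triangle ``index``."""
    areas, normals, centroids = element_geometry(mesh)
    v = mesh.vertices[mesh.triangles[index]]
    g1 = v[1] - v[0]
    g2 = v[2] - v[0]
    metric = np.array([[g1 @ g1, g1 @ g2], [g1 @ g2, g2 @ g2]])
    g_det = float(np.linalg.det(metric))
    return MembraneElement(
        g1=g1, g2=g2, metric=metric, g_det=g_det,
        normal=normals[index], centroid=centroids[index],
        area=float(areas[index]),
    )


@dataclass
class StressField:
    """Per-element membrane stress state (N/cm^2).

    ``sigma`` holds centroid contravariant components (s11, s12, s22) in the
    element covariant basis; ``global_tensor`` the corresponding 3x3 surface
    Cauchy tensor in global coordinates (zero eigenvalue along the normal);
    ``principal_1 >= principal_2`` are the in-plane principal stresses.
    """

    sigma: np.ndarray  # (F, 3)
    principal_1: np.ndarray  # (F,)
    principal_2: np.ndarray  # (F,)
    global_tensor: np.ndarray  # (F, 3, 3)
    nodal: np.ndarray = None  # (V, 3) components in vertex tangent frames
    areas: np.ndarray = None  # (F,) element areas, cm^2
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

# gradients of the linear shape functions on the reference triangle
_DN = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # (node, xi)


def vertex_tangent_frames(mesh: SurfaceMesh):
    """Orthonormal tangent frame (f1, f2) and unit normal at every vertex.

    Vertex normals are area-weighted averages of incident element normals;
    f1 is an arbitrary but deterministic in-plane direction.
    """
    areas, normals, _ = element_geometry(mesh)
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.triangles[:, k], normals * areas[:, None])
    norms = np.linalg.norm(vn, axis=1)
    if np.any(norms == 0):
        raise ValueError("isolated vertex with no incident faces")
    vn /= norms[:, None]
    # pick the global axis least aligned with n to seed the frame
    seed = np.eye(3)[np.argmin(np.abs(vn), axis=1)]
    f1 = seed - (np.sum(seed * vn, axis=1))[:, None] * vn
    f1 /= np.linalg.norm(f1, axis=1)[:, None]
    f2 = np.cross(vn, f1)
    return f1, f2, vn


def assemble_equilibrium(mesh: SurfaceMesh, load: LoadCase):
    """Assemble the discrete membrane equilibrium system A x = b.

    Unknowns ``x``: three stress components per vertex in that vertex's
    tangent frame (s11, s12, s22), 3V total.  Equations: three per free
    vertex (force balance along x, y, z); boundary-ring vertices contribute
    no equations.  Returns (A, b, info) with A sparse CSR and ``info``
    carrying the free-vertex map, frames, and per-element data needed for
    post-processing.
    """
    V = mesh.n_vertices
    F = mesh.n_triangles
    if F == 0:
        raise ValueError("empty mesh")
    is_closed = mesh.boundary_loop_count() == 0
    if not is_closed and len(mesh.boundary_vertices) == 0:
        raise ValueError("open mesh without labeled boundary rings")
    fixed = set(int(v) for v in mesh.boundary_vertices)
    if len(fixed) >= V:
        raise ValueError("all vertices on the boundary; no free equations")

    areas, normals, centroids = element_geometry(mesh)
    f1, f2, _ = vertex_tangent_frames(mesh)
    h = load.thickness_h
    p = load.pressure_internal

    verts = mesh.vertices
    tris = mesh.triangles
    g1 = verts[tris[:, 1]] - verts[tris[:, 0]]  # (F, 3)
    g2 = verts[tris[:, 2]] - verts[tris[:, 0]]
    sqrt_g = 2.0 * areas

    # dual (contravariant) in-plane basis: [g^1 g^2]^T = G^{-1} [g1 g2]^T
    G = np.empty((F, 2, 2))
    G[:, 0, 0] = np.einsum("ij,ij->i", g1, g1)
    G[:, 0, 1] = G[:, 1, 0] = np.einsum("ij,ij->i", g1, g2)
    G[:, 1, 1] = np.einsum("ij,ij->i", g2, g2)
    Ginv = np.linalg.inv(G)
    gd1 = Ginv[:, 0, 0, None] * g1 + Ginv[:, 0, 1, None] * g2  # g^1
    gd2 = Ginv[:, 1, 0, None] * g1 + Ginv[:, 1, 1, None] * g2  # g^2

    # per (element, node): 3x3 map C from nodal frame components
    # (s11, s12, s22) to element contravariant (sig11, sig12, sig22)
    # via the physical tensor T = s11 f1f1 + s12 (f1f2 + f2f1) + s22 f2f2,
    # sig^{ab} = g^a . T . g^b
    rows, cols, vals = [], [], []
    b = np.zeros(3 * V)
    row_mask = np.zeros(3 * V, dtype=bool)  # rows that carry equations

    a1 = np.einsum("fj,fnj->fn", gd1,
                   np.stack([f1[tris[:, k]] for k in range(3)], axis=1))
    a2 = np.einsum("fj,fnj->fn", gd2,
                   np.stack([f1[tris[:, k]] for k in range(3)], axis=1))
    b1 = np.einsum("fj,fnj->fn", gd1,
                   np.stack([f2[tris[:, k]] for k in range(3)], axis=1))
    b2 = np.einsum("fj,fnj->fn", gd2,
                   np.stack([f2[tris[:, k]] for k in range(3)], axis=1))
    # C[f, n, out(3), in(3)].  The nodal shear unknown is stored scaled by
    # sqrt(2) so that the Euclidean norm of the unknown vector equals the
    # Frobenius norm of the nodal stress tensors — this makes the
    # minimum-norm (damped) solution invariant under rigid rotations of the
    # mesh (the tangent-frame seeds are arbitrary).
    s2 = np.sqrt(2.0)
    C = np.empty((F, 3, 3, 3))
    C[..., 0, 0] = a1 * a1
    C[..., 0, 1] = 2 * a1 * b1 / s2
    C[..., 0, 2] = b1 * b1
    C[..., 1, 0] = a1 * a2
    C[..., 1, 1] = (a1 * b2 + b1 * a2) / s2
    C[..., 1, 2] = b1 * b2
    C[..., 2, 0] = a2 * a2
    C[..., 2, 1] = 2 * a2 * b2 / s2
    C[..., 2, 2] = b2 * b2

    # internal force at test node a from element f:
    #   f_a = h sqrt_g sum_b (1/6) [ dNa1 (g1 s11_b + g2 s12_b)
    #                              + dNa2 (g1 s12_b + g2 s22_b) ]
    # columns couple to trial node b's unknowns through C[f, b]
    for a in range(3):  # test node
        va = tris[:, a]  # (F,)
        free = ~np.isin(va, list(fixed)) if fixed else np.ones(F, bool)
        # direction vectors multiplying each contravariant component
        d_s11 = _DN[a, 0] * g1  # (F, 3)
        d_s12 = _DN[a, 0] * g2 + _DN[a, 1] * g1
        d_s22 = _DN[a, 1] * g2
        D = np.stack([d_s11, d_s12, d_s22], axis=2)  # (F, 3dir, 3contr)
        for bnode in range(3):  # trial node
            vb = tris[:, bnode]
            # (F, 3dir, 3in): D @ C[f, bnode]
            M = (h * sqrt_g / 6.0)[:, None, None] * np.einsum(
                "fdc,fci->fdi", D, C[:, bnode])
            fsel = np.nonzero(free)[0]
            for d in range(3):
                for i in range(3):
                    rows.append(3 * va[fsel] + d)
                    cols.append(3 * vb[fsel] + i)
                    vals.append(M[fsel, d, i])
        # consistent pressure load p A/3 n at test node
        load_vec = (p * areas / 3.0)[:, None] * normals
        for d in range(3):
            np.add.at(b, 3 * va[free] + d, load_vec[free, d])
        row_mask[np.unique(3 * va[free])] = True
        row_mask[np.unique(3 * va[free] + 1)] = True
        row_mask[np.unique(3 * va[free] + 2)] = True

    A_full = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * V, 3 * V),
    ).tocsr()
    keep = np.nonzero(row_mask)[0]
    A = A_full[keep]
    b_kept = b[keep]
    info = {
        "free_rows": keep,
        "fixed_vertices": np.array(sorted(fixed), dtype=np.int64),
        "frames": (f1, f2),
        "A_full": A_full,
        "b_full": b,
        "areas": areas,
        "normals": normals,
        "element_data": (g1, g2, sqrt_g, C),
        "closed": is_closed,
    }
    return A, b_kept, info


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------

class SolverError(RuntimeError):
    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


def solve_stress(mesh: SurfaceMesh, load: LoadCase,
                 reg_scale: float = 1e-6, newton_iters: int = 1,
                 residual_tol: float = 0.05) -> StressField:
    """Solve the inverse membrane problem for the Cauchy stress field.

    Minimum-Frobenius-norm least squares via the Tikhonov-damped normal
    equations (damping ``reg_scale * ||A||_F^2 / dof``, sparse LU); an
    optional damped-Newton outer loop is retained for formulations with
    geometric nonlinearity — for the fixed imaged configuration the system
    is linear and converges in one step.  Raises :class:`SolverError` when
    the final equation residual exceeds ``residual_tol`` of the load norm.
    """
    A, b, info = assemble_equilibrium(mesh, load)
    dof = A.shape[1]
    fro2 = (A.multiply(A)).sum()
    damp2 = reg_scale * fro2 / dof

    # damped normal equations, sparse LU: deterministic and exact for the
    # regularized problem (the system is linear in the stress unknowns)
    H = (A.T @ A + damp2 * sp.identity(dof)).tocsc()
    lu = splu(H)
    x = np.zeros(dof)
    for _ in range(max(1, newton_iters)):
        # Newton step on the damped objective; zero from the second
        # iteration on since the system is linear
        grad = A.T @ (A @ x - b) + damp2 * x
        dx = lu.solve(-grad)
        x = x + dx
        if np.linalg.norm(dx) <= 1e-14 * max(np.linalg.norm(x), 1.0):
            break

    load_norm = np.linalg.norm(b)
    resid = float(np.linalg.norm(A @ x - b))
    rel = resid / load_norm if load_norm > 0 else resid
    if load_norm > 0 and rel > residual_tol:
        raise SolverError(
            f"equilibrium residual {rel:.3e} exceeds tolerance "
            f"{residual_tol:.1e}", residual=resid)

    field = _postprocess(mesh, x, info)
    # boundary reactions: residuals of the excluded (boundary) equations
    full_res = info["A_full"] @ x - info["b_full"]
    reactions = full_res.reshape(-1, 3)
    total_load = (info["b_full"]).reshape(-1, 3).sum(axis=0)
    field.diagnostics.update(
        residual=resid,
        relative_residual=rel,
        damp=float(np.sqrt(damp2)),
        reaction_sum=reactions.sum(axis=0),
        total_load=total_load,
        force_balance_error=float(
            np.linalg.norm(reactions.sum(axis=0))
            / max(np.linalg.norm(info["b_full"]), 1e-30)),
    )
    return field


def _postprocess(mesh: SurfaceMesh, x: np.ndarray, info: dict) -> StressField:
    tris = mesh.triangles
    F = len(tris)
    g1, g2, sqrt_g, C = info["element_data"]
    scaled = x.reshape(-1, 3)
    nodal = scaled.copy()
    nodal[:, 1] /= np.sqrt(2.0)  # undo the Frobenius shear scaling
    # centroid contravariant components: average of the three nodal values
    # mapped into the element basis
    s_nodes = np.einsum("fnoi,fni->fno", C,
                        scaled[tris])  # (F, node, 3 contravariant)
    sigma = s_nodes.mean(axis=1)  # (F, 3)
    # physical tensor T = sig^{ab} g_a (x) g_b
    T = (sigma[:, 0, None, None] * np.einsum("fi,fj->fij", g1, g1)
         + sigma[:, 1, None, None] * (np.einsum("fi,fj->fij", g1, g2)
                                      + np.einsum("fi,fj->fij", g2, g1))
         + sigma[:, 2, None, None] * np.einsum("fi,fj->fij", g2, g2))
    p1, p2 = _principal_from_tensor(T, g1, info["normals"])
    return StressField(sigma=sigma, principal_1=p1, principal_2=p2,
                       global_tensor=T, nodal=nodal, areas=info["areas"])


def _principal_from_tensor(T: np.ndarray, g1: np.ndarray,
                           normals: np.ndarray):
    e1 = g1 / np.linalg.norm(g1, axis=1)[:, None]
    e2 = np.cross(normals, e1)
    t11 = np.einsum("fi,fij,fj->f", e1, T, e1)
    t12 = np.einsum("fi,fij,fj->f", e1, T, e2)
    t22 = np.einsum("fi,fij,fj->f", e2, T, e2)
    mean = 0.5 * (t11 + t22)
    radius = np.sqrt(0.25 * (t11 - t22) ** 2 + t12 ** 2)
    return mean + radius, mean - radius


def principal_stresses(sigma: np.ndarray, element: MembraneElement):
    """In-plane principal stresses (descending) from contravariant
    components (s11, s12, s22) and the element's covariant basis."""
    s11, s12, s22 = np.asarray(sigma, dtype=float)
    g1, g2 = element.g1, element.g2
    T = (s11 * np.outer(g1, g1)
         + s12 * (np.outer(g1, g2) + np.outer(g2, g1))
         + s22 * np.outer(g2, g2))
    e1 = g1 / np.linalg.norm(g1)
    e2 = np.cross(element.normal, e1)
    t11, t12, t22 = e1 @ T @ e1, e1 @ T @ e2, e2 @ T @ e2
    mean = 0.5 * (t11 + t22)
    radius = np.sqrt(0.25 * (t11 - t22) ** 2 + t12 ** 2)
    return float(mean + radius), float(mean - radius)
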