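"""Taylor–Hood P2–P1 finite elements on triangles.

Velocity is approximated with continuous piecewise quadratics (nodes at
vertices and edge midpoints, two components per node, interleaved DOF
numbering ``2*node + component``), pressure with continuous piecewise
linears at the vertices.  This pair satisfies the discrete inf–sup
condition, so no pressure stabilization is needed.

Assembled operators (per subdomain, on the deformed physical mesh):

* ``M``   mass, weighted by the fluid density rho_f,
* ``K``   viscous stiffness in strain-rate form, 2 mu_f int eps(u):eps(v),
* ``D``   divergence, D[c, (b,j)] = -int (d_j phi_b) psi_c,
* ``C(u)``  convective matrix int rho_f [(u.grad) phi_b] . phi_a,
* ``C'(u)`` its directional counterpart int rho_f [(phi_b.grad) u] . phi_a
  (needed for the exact Newton tangent),
* ``X_u`` full H^1 inner product with unit coefficients, ``X_p`` the
  pressure L^2 mass matrix.

Quadrature is a 7-point degree-5 rule, exact for every bilinear form here
with P2 data (the convective integrand is degree 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mesh import TriMesh

__all__ = [
    "FluidProperties",
    "TaylorHoodSpace",
    "OperatorSet",
    "build_taylor_hood_space",
    "assemble_constant_operators",
    "assemble_convective",
    "assemble_convective_directional",
    "assemble_norm_matrices",
    "wall_shear_stress",
    "taylor_hood_dof_counts",
]


@dataclass
class FluidProperties:
    """Fluid density and dynamic viscosity in CGS units."""

    rho_f: float = 1.06  # g / cm^3
    mu_f: float = 4.0e-2  # g / (cm s)

    def __post_init__(self):
        if self.rho_f <= 0 or self.mu_f <= 0:
            raise ValueError("density and viscosity must be positive")


# 7-point Dunavant rule, degree of exactness 5, on the reference triangle
_QW = np.array(
    [0.225, 0.13239415278850618, 0.13239415278850618, 0.13239415278850618,
     0.12593918054482715, 0.12593918054482715, 0.12593918054482715]
) * 0.5
_a, _b = 0.470142064105115090, 0.797426985353087322
_QP = np.array(
    [[1 / 3, 1 / 3],
     [_a, _a], [1 - 2 * _a, _a], [_a, 1 - 2 * _a],
     [_b, (1 - _b) / 2], [(1 - _b) / 2, _b], [(1 - _b) / 2, (1 - _b) / 2]]
)


def _p2_shape(xy: np.ndarray):
    """P2 shape values and reference gradients at points (q, 2).

    Local node order: vertices 0,1,2 then midpoints of edges (0,1), (1,2),
    (2,0).  Returns (N (q,6), dN (q,6,2))."""
    x, y = xy[:, 0], xy[:, 1]
    l0, l1, l2 = 1 - x - y, x, y
    N = np.stack(
        [l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
         4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0], axis=1
    )
    dl = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    L = np.stack([l0, l1, l2], axis=1)  # (q, 3)
    dN = np.empty((xy.shape[0], 6, 2))
    for v in range(3):
        dN[:, v, :] = (4 * L[:, v:v + 1] - 1) * dl[v]
    pairs = [(0, 1), (1, 2), (2, 0)]
    for m, (i, j) in enumerate(pairs):
        dN[:, 3 + m, :] = 4 * (L[:, i:i + 1] * dl[j] + L[:, j:j + 1] * dl[i])
    return N, dN


def _p1_shape(xy: np.ndarray):
    x, y = xy[:, 0], xy[:, 1]
    N = np.stack([1 - x - y, x, y], axis=1)
    dN = np.broadcast_to(
        np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]]), (xy.shape[0], 3, 2)
    )
    return N, dN


_P2N, _P2D = _p2_shape(_QP)
_P1N, _P1D = _p1_shape(_QP)


@dataclass
class TaylorHoodSpace:
    mesh: TriMesh
    edges: np.ndarray  # (n_edges, 2) sorted vertex pairs
    cell_edges: np.ndarray  # (n_tri, 3) edge index per local edge (0,1),(1,2),(2,0)
    boundary_edge_index: np.ndarray  # (n_bed,) edge index of each tagged boundary edge
    # geometry caches
    jac: np.ndarray = field(repr=False, default=None)  # (n_tri, 2, 2)
    detj: np.ndarray = field(repr=False, default=None)
    invj: np.ndarray = field(repr=False, default=None)

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_points

    @property
    def n_vel_nodes(self) -> int:
        return self.mesh.n_points + self.edges.shape[0]

    @property
    def n_u(self) -> int:
        """Velocity DOF count, 2 * (vertices + edges)."""
        return 2 * self.n_vel_nodes

    @property
    def n_p(self) -> int:
        return self.mesh.n_points

    def vel_node_coords(self) -> np.ndarray:
        mids = 0.5 * (self.mesh.points[self.edges[:, 0]] + self.mesh.points[self.edges[:, 1]])
        return np.vstack([self.mesh.points, mids])

    def cell_vel_nodes(self) -> np.ndarray:
        """(n_tri, 6) global velocity node of each local P2 node."""
        return np.hstack([self.mesh.cells, self.mesh.n_points + self.cell_edges])

    def edge_index(self, v0: int, v1: int) -> int:
        key = (min(v0, v1), max(v0, v1))
        return self._edge_lookup[key]

    def boundary_nodes(self, tag: str) -> np.ndarray:
        """Velocity node indices (vertices + midpoints) on boundary ``tag``."""
        sel = self.mesh.boundary_tags == tag
        bed = self.mesh.boundary_edges[sel]
        eidx = self.boundary_edge_index[sel]
        return np.unique(np.concatenate([bed.ravel(), self.mesh.n_points + eidx]))

    def boundary_dofs(self, tag: str) -> np.ndarray:
        nodes = self.boundary_nodes(tag)
        return np.sort(np.concatenate([2 * nodes, 2 * nodes + 1]))


def build_taylor_hood_space(mesh: TriMesh) -> TaylorHoodSpace:
    cells = mesh.cells
    raw = np.vstack([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    raw_sorted = np.sort(raw, axis=1)
    edges, inv = np.unique(raw_sorted, axis=0, return_inverse=True)
    cell_edges = inv.reshape(3, -1).T

    lookup = {tuple(e): i for i, e in enumerate(edges)}
    bidx = np.array(
        [lookup[tuple(sorted(e))] for e in mesh.boundary_edges], dtype=np.int64
    ) if len(mesh.boundary_edges) else np.empty(0, dtype=np.int64)

    p = mesh.points[cells]
    jac = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)  # d x_phys / d x_ref
    detj = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    if np.any(detj <= 0):
        raise ValueError("mesh contains inverted or degenerate elements")
    invj = np.empty_like(jac)
    invj[:, 0, 0] = jac[:, 1, 1] / detj
    invj[:, 0, 1] = -jac[:, 0, 1] / detj
    invj[:, 1, 0] = -jac[:, 1, 0] / detj
    invj[:, 1, 1] = jac[:, 0, 0] / detj

    space = TaylorHoodSpace(mesh, edges, cell_edges, bidx, jac, detj, invj)
    space._edge_lookup = lookup
    return space


def taylor_hood_dof_counts(d: int, n_vertices: int, n_edges: int):
    """(N_u, N_p) for a P2-P1 pair in ambient dimension d: velocity DOFs sit
    at vertices and edge midpoints, one per component."""
    return d * (n_vertices + n_edges), n_vertices


def _phys_grads(space: TaylorHoodSpace):
    """Physical P2 gradients at quad points: (n_tri, q, 6, 2)."""
    return np.einsum("qak,ekj->eqaj", _P2D, space.invj)


def _scatter(rows, cols, vals, shape):
    return sp.coo_matrix((vals.ravel(), (rows.ravel(), cols.ravel())), shape=shape).tocsr()


def _vel_dof_table(space: TaylorHoodSpace):
    """(n_tri, 12) velocity DOFs, local order (node0x, node0y, node1x, ...)."""
    nodes = space.cell_vel_nodes()
    dofs = np.empty((nodes.shape[0], 12), dtype=np.int64)
    dofs[:, 0::2] = 2 * nodes
    dofs[:, 1::2] = 2 * nodes + 1
    return dofs


@dataclass
class OperatorSet:
    """Constant FE operators of one subdomain plus convective assemblers."""

    space: TaylorHoodSpace
    props: FluidProperties
    M: sp.csr_matrix
    K: sp.csr_matrix
    D: sp.csr_matrix
    X_u: sp.csr_matrix
    X_p: sp.csr_matrix

    def convective(self, u: np.ndarray) -> sp.csr_matrix:
        return assemble_convective(self.space, self.props, u)

    def convective_directional(self, u: np.ndarray) -> sp.csr_matrix:
        return assemble_convective_directional(self.space, self.props, u)


def assemble_constant_operators(space: TaylorHoodSpace, props: FluidProperties) -> OperatorSet:
    """Assemble M, K, D and the norm matrices X_u, X_p."""
    nt = space.mesh.n_cells
    dN = _phys_grads(space)  # (e, q, 6, 2)
    wdet = _QW[None, :] * space.detj[:, None]  # (e, q)

    # scalar mass and H1 blocks (same for both components)
    m_sc = np.einsum("eq,qa,qb->eab", wdet, _P2N, _P2N)
    grad_sc = np.einsum("eq,eqak,eqbk->eab", wdet, dN, dN)

    vdofs = _vel_dof_table(space)
    n_u, n_p = space.n_u, space.n_p

    # vector block-diagonal scatter: component c occupies dofs[:, c::2]
    def vector_from_scalar(blk):
        rows = np.concatenate([
            np.repeat(vdofs[:, 0::2], 6, axis=1).ravel(),
            np.repeat(vdofs[:, 1::2], 6, axis=1).ravel(),
        ])
        cols = np.concatenate([
            np.tile(vdofs[:, 0::2], (1, 6)).ravel(),
            np.tile(vdofs[:, 1::2], (1, 6)).ravel(),
        ])
        vals = np.concatenate([blk.ravel(), blk.ravel()])
        return sp.coo_matrix((vals, (rows, cols)), shape=(n_u, n_u)).tocsr()

    M = props.rho_f * vector_from_scalar(m_sc)
    X_u = vector_from_scalar(m_sc + grad_sc)

    # viscous stiffness: mu * (delta_ij grad.grad + dN_b,i dN_a,j)
    kblk = np.zeros((nt, 12, 12))
    cross = np.einsum("eq,eqbi,eqaj->eaibj", wdet, dN, dN)  # a, i, b, j
    for i in range(2):
        for j in range(2):
            kblk[:, i::2, j::2] = cross[:, :, i, :, j]
            if i == j:
                kblk[:, i::2, j::2] += grad_sc
    kblk *= props.mu_f
    rows = np.repeat(vdofs, 12, axis=1)
    cols = np.tile(vdofs, (1, 12))
    K = _scatter(rows, cols, kblk, (n_u, n_u))

    # divergence D[c,(b,j)] = -sum_q w |J| psi_c dN_b,j
    dblk = -np.einsum("eq,qc,eqbj->ecbj", wdet, _P1N, dN).reshape(nt, 3, 12)
    prow = np.repeat(space.mesh.cells, 12, axis=1)
    pcol = np.tile(vdofs, (1, 3)).reshape(nt, 3, 12)
    D = _scatter(prow, pcol, dblk, (n_p, n_u))

    mp = np.einsum("eq,qa,qb->eab", wdet, _P1N, _P1N)
    X_p = _scatter(
        np.repeat(space.mesh.cells, 3, axis=1), np.tile(space.mesh.cells, (1, 3)),
        mp, (n_p, n_p),
    )
    return OperatorSet(space, props, M, K, D, X_u, X_p)


def _u_at_quad(space: TaylorHoodSpace, u: np.ndarray):
    """Velocity values (e, q, 2) and gradients (e, q, 2, 2) at quad points."""
    vdofs = _vel_dof_table(space)
    ue = u[vdofs].reshape(-1, 6, 2)  # (e, local node, comp)
    vals = np.einsum("qa,eac->eqc", _P2N, ue)
    dN = _phys_grads(space)
    grads = np.einsum("eqaj,eac->eqcj", dN, ue)
    return vals, grads


def assemble_convective(space: TaylorHoodSpace, props: FluidProperties, u: np.ndarray) -> sp.csr_matrix:
    """C(u)[(a,i),(b,j)] = delta_ij int rho_f (u . grad phi_b) phi_a."""
    if u.shape[0] != space.n_u:
        raise ValueError("velocity DOF vector has wrong length")
    vals, _ = _u_at_quad(space, u)
    dN = _phys_grads(space)
    conv = np.einsum("eq,eqk,eqbk,qa->eab", _QW[None, :] * space.detj[:, None], vals, dN, _P2N)
    conv *= props.rho_f
    vdofs = _vel_dof_table(space)
    nt = space.mesh.n_cells
    blk = np.zeros((nt, 12, 12))
    blk[:, 0::2, 0::2] = conv
    blk[:, 1::2, 1::2] = conv
    return _scatter(np.repeat(vdofs, 12, axis=1), np.tile(vdofs, (1, 12)), blk,
                    (space.n_u, space.n_u))


def assemble_convective_directional(space: TaylorHoodSpace, props: FluidProperties, u: np.ndarray) -> sp.csr_matrix:
    """C'(u)[(a,i),(b,j)] = int rho_f phi_b (d_j u_i) phi_a, the derivative of
    the convective term with respect to the transported field."""
    if u.shape[0] != space.n_u:
        raise ValueError("velocity DOF vector has wrong length")
    _, grads = _u_at_quad(space, u)  # (e,q,i,j) = d_j u_i
    wdet = _QW[None, :] * space.detj[:, None]
    blk12 = np.einsum("eq,qa,eqij,qb->eaibj", wdet, _P2N, grads, _P2N) * props.rho_f
    nt = space.mesh.n_cells
    blk = np.zeros((nt, 12, 12))
    for i in range(2):
        for j in range(2):
            blk[:, i::2, j::2] = blk12[:, :, i, :, j]
    vdofs = _vel_dof_table(space)
    return _scatter(np.repeat(vdofs, 12, axis=1), np.tile(vdofs, (1, 12)), blk,
                    (space.n_u, space.n_u))


def assemble_norm_matrices(space: TaylorHoodSpace):
    """(X_u, X_p): full H^1 velocity inner product (unit coefficients) and
    pressure L^2 mass."""
    ops = assemble_constant_operators(space, FluidProperties(rho_f=1.0, mu_f=1.0))
    return ops.X_u, ops.X_p


def load_vector(space: TaylorHoodSpace, f):
    """int f . phi for a callable f(x) -> (m, 2)."""
    qp_phys = np.einsum("qa,eac->eqc", _P1N, space.mesh.points[space.mesh.cells])
    fv = np.asarray(f(qp_phys.reshape(-1, 2))).reshape(qp_phys.shape)
    wdet = _QW[None, :] * space.detj[:, None]
    fe = np.einsum("eq,eqc,qa->eac", wdet, fv, _P2N)  # (e, a, c)
    out = np.zeros(space.n_u)
    nodes = space.cell_vel_nodes()
    for c in range(2):
        np.add.at(out, 2 * nodes + c, fe[:, :, c])
    return out


def interpolate_velocity(space: TaylorHoodSpace, fn) -> np.ndarray:
    """Nodal interpolant of a callable velocity field onto P2 DOFs."""
    xy = space.vel_node_coords()
    vals = np.asarray(fn(xy))
    out = np.empty(space.n_u)
    out[0::2] = vals[:, 0]
    out[1::2] = vals[:, 1]
    return out


def interpolate_pressure(space: TaylorHoodSpace, fn) -> np.ndarray:
    return np.asarray(fn(space.mesh.points)).reshape(-1)


def velocity_errors(space: TaylorHoodSpace, u: np.ndarray, u_exact, grad_exact):
    """(L2 error, H1-seminorm error) of a velocity DOF vector against
    callables u_exact(x)->(m,2), grad_exact(x)->(m,2,2) by quadrature."""
    qp_phys = np.einsum("qa,eac->eqc", _P1N, space.mesh.points[space.mesh.cells])
    flat = qp_phys.reshape(-1, 2)
    ue = np.asarray(u_exact(flat)).reshape(qp_phys.shape)
    ge = np.asarray(grad_exact(flat)).reshape(qp_phys.shape[0], qp_phys.shape[1], 2, 2)
    vals, grads = _u_at_quad(space, u)
    wdet = _QW[None, :] * space.detj[:, None]
    l2 = np.sqrt(np.einsum("eq,eqc->", wdet, (vals - ue) ** 2))
    h1 = np.sqrt(np.einsum("eq,eqcj->", wdet, (grads - ge) ** 2))
    return l2, h1


def pressure_error(space: TaylorHoodSpace, p: np.ndarray, p_exact):
    qp_phys = np.einsum("qa,eac->eqc", _P1N, space.mesh.points[space.mesh.cells])
    pe = np.asarray(p_exact(qp_phys.reshape(-1, 2))).reshape(qp_phys.shape[:2])
    pv = np.einsum("qa,ea->eq", _P1N, p[space.mesh.cells])
    wdet = _QW[None, :] * space.detj[:, None]
    return np.sqrt(np.einsum("eq,eq->", wdet, (pv - pe) ** 2))


def solve_stokes_dirichlet(space: TaylorHoodSpace, props: FluidProperties,
                           u_bc, f) -> tuple[np.ndarray, np.ndarray]:
    """Steady Stokes solve with strong Dirichlet velocity on the whole
    boundary and zero-mean pressure (enforced by a scalar multiplier).

    ``u_bc(x) -> (m, 2)`` supplies boundary values, ``f(x) -> (m, 2)`` the
    body force.  Used for manufactured-solution verification.
    """
    import scipy.sparse.linalg as spla

    ops = assemble_constant_operators(space, props)
    n_u, n_p = space.n_u, space.n_p
    bnodes = np.unique(np.concatenate([space.boundary_nodes(t) for t in space.mesh.tags()]))
    bdofs = np.concatenate([2 * bnodes, 2 * bnodes + 1])
    free = np.setdiff1d(np.arange(n_u), bdofs)

    xy = space.vel_node_coords()
    u_full = np.zeros(n_u)
    vals = np.asarray(u_bc(xy[bnodes]))
    u_full[2 * bnodes] = vals[:, 0]
    u_full[2 * bnodes + 1] = vals[:, 1]

    F = load_vector(space, f)
    rhs_u = (F - ops.K @ u_full)[free]
    rhs_p = -(ops.D @ u_full)

    Kff = ops.K[np.ix_(free, free)]
    Df = ops.D[:, free]
    pint = np.asarray(ops.X_p.sum(axis=1)).ravel()  # int psi_c
    A = sp.bmat(
        [[Kff, Df.T, None],
         [Df, None, pint[:, None]],
         [None, pint[None, :], None]], format="csc"
    )
    rhs = np.concatenate([rhs_u, rhs_p, [0.0]])
    sol = spla.spsolve(A, rhs)
    u_full[free] = sol[: free.size]
    p = sol[free.size: free.size + n_p]
    return u_full, p


def wall_shear_stress(space: TaylorHoodSpace, props: FluidProperties,
                      u: np.ndarray, p: np.ndarray | None = None,
                      wall_tag: str = "wall"):
    """WSS magnitude per wall facet, evaluated at facet midpoints.

    The traction is sigma(u, p) n = 2 mu_f eps(u) n - p n; its tangential
    part is independent of the pressure (the -p n term is purely normal),
    so ``p`` is accepted for interface uniformity but not used.
    Returns (midpoints (m, 2), wss (m,)).
    """
    mesh = space.mesh
    sel = np.where(mesh.boundary_tags == wall_tag)[0]
    if sel.size == 0:
        raise ValueError(f"no boundary facets tagged '{wall_tag}'")
    # adjacent triangle of each boundary edge
    edge_cells = {}
    for t, c in enumerate(mesh.cells):
        for a, b in ((c[0], c[1]), (c[1], c[2]), (c[2], c[0])):
            edge_cells.setdefault((min(a, b), max(a, b)), []).append(t)
    mids, wss = [], []
    vdofs = _vel_dof_table(space)
    for k in sel:
        v0, v1 = mesh.boundary_edges[k]
        t = edge_cells[(min(v0, v1), max(v0, v1))][0]
        pts = mesh.points[mesh.cells[t]]
        mid = 0.5 * (mesh.points[v0] + mesh.points[v1])
        # reference coordinates of the midpoint in triangle t
        A = np.column_stack([pts[1] - pts[0], pts[2] - pts[0]])
        ref = np.linalg.solve(A, mid - pts[0])
        _, dN = _p2_shape(ref[None, :])
        dN_phys = dN[0] @ space.invj[t]
        ue = u[vdofs[t]].reshape(6, 2)
        grad = ue.T @ dN_phys  # (i, j) = d_j u_i
        eps = 0.5 * (grad + grad.T)
        tang = mesh.points[v1] - mesh.points[v0]
        tang = tang / np.linalg.norm(tang)
        nrm = np.array([tang[1], -tang[0]])
        # outward: pointing away from the triangle's interior (its centroid)
        if np.dot(nrm, mid - pts.mean(axis=0)) < 0:
            nrm = -nrm
        trac = 2 * props.mu_f * eps @ nrm
        trac_t = trac - np.dot(trac, nrm) * nrm
        mids.append(mid)
        wss.append(np.linalg.norm(trac_t))
    return np.array(mids), np.array(wss)
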