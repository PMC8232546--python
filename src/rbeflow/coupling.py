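"""Nonconforming coupling of subdomains and the global block system.

Velocity continuity across each internal interface and the inlet Dirichlet
data are imposed weakly against the spectral multiplier basis: on interface
``i`` with sides j ("+", sign +1) and m ("-", sign -1),

    B[i]j u^j + B[i]m u^m = 0,        B_pq = int_Gamma  xi_p . phi_q,

with both one-sided matrices assembled by facet quadrature on the side's
own mesh — no cross-interface interpolation ever happens.  The coupled
unknown is Y = (W, Lambda) with W = (u^1, p^1, ..., u^N, p^N) (wall DOFs
eliminated strongly) and Lambda the multipliers of the internal interfaces
followed by the inlets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .fem import (FluidProperties, OperatorSet, TaylorHoodSpace,
                  assemble_constant_operators, build_taylor_hood_space)
from .geometry import InterfaceDescriptor, ModularGeometry, Subdomain
from .interface_basis import InterfaceBasis, InterfaceMap, map_to_interface

__all__ = [
    "assemble_interface_coupling",
    "parabolic_inflow",
    "assemble_inlet_coupling",
    "SubdomainOperators",
    "GlobalSystem",
    "build_global_system",
    "multiplier_dof_count",
]

_EDGE_QP, _EDGE_QW = np.polynomial.legendre.leggauss(6)
_EDGE_QP = 0.5 * (_EDGE_QP + 1.0)  # [0, 1]
_EDGE_QW = 0.5 * _EDGE_QW


def _p2_trace(s: np.ndarray):
    """P2 trace shape functions along an edge: (v0, v1, midpoint)."""
    return np.stack([(1 - s) * (1 - 2 * s), s * (2 * s - 1), 4 * s * (1 - s)], axis=1)


def assemble_interface_coupling(space: TaylorHoodSpace, tag: str,
                                basis: InterfaceBasis, iface: InterfaceMap) -> sp.csr_matrix:
    """One-sided coupling matrix (n_lambda x n_u) for boundary ``tag``.

    ``iface`` is the canonical map of the interface (the "+"-side frame);
    the orientation sign is carried by ``iface.sign``.
    """
    mesh = space.mesh
    sel = np.where(mesh.boundary_tags == tag)[0]
    if sel.size == 0:
        raise ValueError(f"no boundary facets tagged '{tag}' on this mesh")
    evaluate = map_to_interface(basis, iface)
    tr = _p2_trace(_EDGE_QP)  # (q, 3)
    rows, cols, vals = [], [], []
    for k in sel:
        v0, v1 = mesh.boundary_edges[k]
        eidx = space.boundary_edge_index[k]
        x0, x1 = mesh.points[v0], mesh.points[v1]
        length = np.linalg.norm(x1 - x0)
        xq = x0[None, :] + _EDGE_QP[:, None] * (x1 - x0)[None, :]
        xi = evaluate(xq)  # (n_lambda, q, 2)
        nodes = np.array([v0, v1, mesh.n_points + eidx])
        # (n_lambda, 3 nodes, 2 comps)
        blk = np.einsum("q,iqc,qa->iac", _EDGE_QW * length, xi, tr)
        for c in range(2):
            dofs = 2 * nodes + c
            rows.append(np.repeat(np.arange(basis.n_lambda), 3))
            cols.append(np.tile(dofs, basis.n_lambda))
            vals.append(blk[:, :, c].ravel())
    B = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(basis.n_lambda, space.n_u),
    )
    return B.tocsr()


def parabolic_inflow(desc: InterfaceDescriptor, Q: float = 1.0):
    """Unit-depth parabolic inflow profile through a segment interface.

    Returns a callable ``g(x) -> (m, 2)`` with flux int g.n = -Q (inflow
    against the outward normal); the peak speed is 3Q/(4R) at the centre.
    """
    if desc.halfwidth <= 0:
        raise ValueError("zero-radius inlet")
    R = desc.halfwidth
    tang = np.array([-desc.normal[1], desc.normal[0]])
    peak = 3.0 * Q / (4.0 * R)

    def g(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        s = (x - desc.center) @ tang / R
        prof = peak * np.clip(1.0 - s**2, 0.0, None)
        return -prof[:, None] * desc.normal[None, :]

    return g


def inflow_dof_vector(space: TaylorHoodSpace, tag: str, g) -> np.ndarray:
    """Interpolate a boundary profile onto the velocity space (zero away
    from the tagged boundary)."""
    out = np.zeros(space.n_u)
    nodes = space.boundary_nodes(tag)
    xy = space.vel_node_coords()[nodes]
    vals = np.asarray(g(xy))
    out[2 * nodes] = vals[:, 0]
    out[2 * nodes + 1] = vals[:, 1]
    return out


def assemble_inlet_coupling(space: TaylorHoodSpace, tag: str, basis: InterfaceBasis,
                            desc: InterfaceDescriptor):
    """(B_in, rhs_of(g)) for weak inlet Dirichlet: B_in u = B_in g^h."""
    iface = InterfaceMap(desc.center, desc.normal, desc.halfwidth, sign=1)
    B_in = assemble_interface_coupling(space, tag, basis, iface)

    def rhs_of(g_dof: np.ndarray) -> np.ndarray:
        return B_in @ g_dof

    return B_in, rhs_of


@dataclass
class SubdomainOperators:
    """FE operators of one subdomain with wall DOFs eliminated."""

    subdomain: Subdomain
    space: TaylorHoodSpace
    ops: OperatorSet
    free: np.ndarray  # free velocity DOFs (non-wall)
    props: FluidProperties

    @classmethod
    def build(cls, sd: Subdomain, props: FluidProperties) -> "SubdomainOperators":
        space = build_taylor_hood_space(sd.mesh)
        ops = assemble_constant_operators(space, props)
        wall = space.boundary_dofs(sd.block.wall_tag)
        free = np.setdiff1d(np.arange(space.n_u), wall)
        return cls(sd, space, ops, free, props)

    @property
    def n_uf(self) -> int:
        return self.free.size

    @property
    def n_p(self) -> int:
        return self.space.n_p

    @property
    def n_w(self) -> int:
        return self.n_uf + self.n_p

    def full_velocity(self, u_free: np.ndarray) -> np.ndarray:
        u = np.zeros(self.space.n_u)
        u[self.free] = u_free
        return u

    def K_ff(self) -> sp.csr_matrix:
        return self.ops.K[np.ix_(self.free, self.free)]

    def M_ff(self) -> sp.csr_matrix:
        return self.ops.M[np.ix_(self.free, self.free)]

    def D_f(self) -> sp.csr_matrix:
        return self.ops.D[:, self.free]

    def C_ff(self, u_free: np.ndarray) -> sp.csr_matrix:
        C = self.ops.convective(self.full_velocity(u_free))
        return C[np.ix_(self.free, self.free)]

    def C2_ff(self, u_free: np.ndarray) -> sp.csr_matrix:
        C2 = self.ops.convective_directional(self.full_velocity(u_free))
        return C2[np.ix_(self.free, self.free)]

    def saddle_block(self, u_free: np.ndarray | None, newton: bool = False) -> sp.csr_matrix:
        """[[K (+C (+C')), D^T], [D, 0]] on free DOFs."""
        A = self.K_ff()
        if u_free is not None:
            A = A + self.C_ff(u_free)
            if newton:
                A = A + self.C2_ff(u_free)
        return sp.bmat([[A, self.D_f().T], [self.D_f(), None]], format="csr")

    def mass_block(self) -> sp.csr_matrix:
        n = self.n_w
        H = sp.lil_matrix((n, n))
        H[: self.n_uf, : self.n_uf] = self.M_ff()
        return H.tocsr()


def multiplier_dof_count(geometry: ModularGeometry, basis: InterfaceBasis) -> int:
    """Total Lagrange-multiplier DOFs: (internal interfaces + inlets) * N_lambda."""
    return (len(geometry.internal) + len(geometry.inlets)) * basis.n_lambda


@dataclass
class GlobalSystem:
    """The coupled block system over Y = (W, Lambda)."""

    geometry: ModularGeometry
    basis: InterfaceBasis
    props: FluidProperties
    blocks: list  # SubdomainOperators per subdomain
    B_rows: list  # per multiplier group: dict subdomain -> (n_lambda x n_uf) csr
    inlet_rhs: list = field(default_factory=list)  # callables g_dof(t) -> constraint rhs
    inflow: object = None  # Q(t) callable
    _B_cache: object = field(default=None, repr=False)
    _H_cache: object = field(default=None, repr=False)

    # --- layout -----------------------------------------------------------
    @property
    def w_offsets(self):
        off = [0]
        for b in self.blocks:
            off.append(off[-1] + b.n_w)
        return off

    @property
    def n_W(self) -> int:
        return self.w_offsets[-1]

    @property
    def n_groups(self) -> int:
        return len(self.B_rows)

    @property
    def n_Lambda(self) -> int:
        return self.n_groups * self.basis.n_lambda

    @property
    def n_Y(self) -> int:
        return self.n_W + self.n_Lambda

    def split(self, Y: np.ndarray):
        return Y[: self.n_W], Y[self.n_W:]

    def subdomain_state(self, Y: np.ndarray, j: int):
        off = self.w_offsets
        w = Y[off[j]: off[j + 1]]
        b = self.blocks[j]
        return w[: b.n_uf], w[b.n_uf:]

    # --- operators --------------------------------------------------------
    def B_matrix(self) -> sp.csr_matrix:
        """Global coupling matrix (n_Lambda x n_W)."""
        if self._B_cache is not None:
            return self._B_cache
        nl = self.basis.n_lambda
        off = self.w_offsets
        rows = []
        for gi, group in enumerate(self.B_rows):
            cols = []
            for j, b in enumerate(self.blocks):
                if j in group:
                    Bju = group[j]
                    cols.append(sp.hstack([Bju, sp.csr_matrix((nl, b.n_p))]))
                else:
                    cols.append(sp.csr_matrix((nl, b.n_w)))
            rows.append(sp.hstack(cols))
        if not rows:
            self._B_cache = sp.csr_matrix((0, self.n_W))
        else:
            self._B_cache = sp.vstack(rows).tocsr()
        return self._B_cache

    def A_matrix(self, W: np.ndarray, newton: bool = False,
                 frozen: bool = False) -> sp.csr_matrix:
        off = self.w_offsets
        blocks = []
        for j, b in enumerate(self.blocks):
            u = None if frozen else W[off[j]: off[j] + b.n_uf]
            blocks.append(b.saddle_block(u, newton=newton))
        return sp.block_diag(blocks, format="csr")

    def H_matrix(self) -> sp.csr_matrix:
        if self._H_cache is None:
            H_W = sp.block_diag([b.mass_block() for b in self.blocks], format="csr")
            pad = self.n_Lambda
            self._H_cache = sp.block_diag(
                [H_W, sp.csr_matrix((pad, pad))], format="csr"
            )
        return self._H_cache

    def G_vector(self, t: float) -> np.ndarray:
        """Constraint right-hand side (internal rows zero, inlet rows B g)."""
        G = np.zeros(self.n_Lambda)
        nl = self.basis.n_lambda
        n_int = len(self.geometry.internal)
        for k, rhs_fn in enumerate(self.inlet_rhs):
            G[(n_int + k) * nl: (n_int + k + 1) * nl] = rhs_fn(t)
        return G

    def F0(self, t: float, Y: np.ndarray) -> np.ndarray:
        """F_circ(t, Y) = [F(t); G(t)] - [[A(W), B^T], [B, 0]] Y."""
        W, Lam = self.split(Y)
        B = self.B_matrix()
        out = np.zeros(self.n_Y)
        out[self.n_W:] = self.G_vector(t) - B @ W
        AW = self.A_matrix(W) @ W
        out[: self.n_W] = -(AW + B.T @ Lam)
        return out

    def steady_matrix(self, W: np.ndarray, newton: bool = False,
                      frozen: bool = False) -> sp.csr_matrix:
        """[[A(W) (+ Newton term), B^T], [B, 0]] = -dF0/dY."""
        B = self.B_matrix()
        A = self.A_matrix(W, newton=newton, frozen=frozen)
        return sp.bmat([[A, B.T], [B, None]], format="csr")

    # --- diagnostics ------------------------------------------------------
    def interface_fluxes(self, Y: np.ndarray) -> np.ndarray:
        """Flux int u.n through each internal interface, computed from the
        "+" side with the canonical interface normal."""
        out = []
        for (j, nj, m, nm, desc) in self.geometry.internal:
            out.append(self._side_flux(Y, j, nj, desc))
        return np.array(out)

    def inlet_fluxes(self, Y: np.ndarray) -> np.ndarray:
        out = []
        for (j, name, desc) in self.geometry.inlets:
            out.append(self._side_flux(Y, j, name, desc))
        return np.array(out)

    def _side_flux(self, Y, j, tag, desc):
        b = self.blocks[j]
        u = b.full_velocity(self.subdomain_state(Y, j)[0])
        mesh = b.space.mesh
        sel = np.where(mesh.boundary_tags == tag)[0]
        tr = _p2_trace(_EDGE_QP)
        flux = 0.0
        for k in sel:
            v0, v1 = mesh.boundary_edges[k]
            eidx = b.space.boundary_edge_index[k]
            x0, x1 = mesh.points[v0], mesh.points[v1]
            length = np.linalg.norm(x1 - x0)
            nodes = np.array([v0, v1, mesh.n_points + eidx])
            uv = np.stack([u[2 * nodes], u[2 * nodes + 1]], axis=1)  # (3, 2)
            uq = tr @ uv  # (q, 2)
            flux += np.sum(_EDGE_QW * length * (uq @ desc.normal))
        return flux

    def continuity_residual(self, Y: np.ndarray) -> float:
        """max |B W - G| over internal interface rows."""
        W, _ = self.split(Y)
        r = self.B_matrix() @ W
        n_int = len(self.geometry.internal) * self.basis.n_lambda
        if n_int == 0:
            return 0.0
        return float(np.abs(r[:n_int]).max())


def build_global_system(geometry: ModularGeometry, basis: InterfaceBasis,
                        props: FluidProperties, inflow=None) -> GlobalSystem:
    """Assemble all per-subdomain operators and coupling rows.

    ``inflow`` is a callable Q(t); the inlet profile is parabolic with that
    instantaneous flow rate.
    """
    blocks = [SubdomainOperators.build(sd, props) for sd in geometry.subdomains]
    B_rows = []
    for (j, nj, m, nm, desc) in geometry.internal:
        iface_p = InterfaceMap(desc.center, desc.normal, desc.halfwidth, sign=1)
        iface_m = InterfaceMap(desc.center, desc.normal, desc.halfwidth, sign=-1)
        Bj = assemble_interface_coupling(blocks[j].space, nj, basis, iface_p)
        Bm = assemble_interface_coupling(blocks[m].space, nm, basis, iface_m)
        B_rows.append({j: Bj[:, blocks[j].free], m: Bm[:, blocks[m].free]})

    system = GlobalSystem(geometry, basis, props, blocks, B_rows, [], inflow)
    for (j, name, desc) in geometry.inlets:
        B_in, _ = assemble_inlet_coupling(blocks[j].space, name, basis, desc)
        system.B_rows.append({j: B_in[:, blocks[j].free]})
        unit_g = parabolic_inflow(desc, 1.0)
        g_dof = inflow_dof_vector(blocks[j].space, name, unit_g)
        rhs_full = B_in @ g_dof

        def rhs_fn(t, rhs_full=rhs_full):
            q = 1.0 if inflow is None else inflow(t)
            return q * rhs_full

        system.inlet_rhs.append(rhs_fn)
    return system
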