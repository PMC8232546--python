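"""Online phase: reduced coupled system, frozen tangent, error metrics.

Per subdomain the velocity trial space is the span of the Piola
pushforwards of the block's reduced basis onto the deformed subdomain; the
pressure basis is used unchanged (DOF-wise).  All FE operators of the
deformed subdomains are projected by congruence, the multiplier space is
kept at full (small) size, and the time-stepping/Newton machinery of the
full order model is reused verbatim on the reduced state
Y^N = (u^{1,N}, p^{1,N}, ..., Lambda).

The Newton tangent is by default the *frozen* linearization that drops the
convective term: it is constant in time, so its block factorizations and
the reduced Schur complement over the multipliers are computed once per
simulation.  The convective part of the residual is evaluated either by
direct projection (assemble C(V u^N) and project) or by contracting the
precomputed third-order tensor

    T[i, l, m] = int rho_f [(zeta_m . grad) zeta_l] . zeta_i,

optionally truncated to the first N_c modes in l and m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .coupling import GlobalSystem
from .offline import BasisArchive, piola_pullback, piola_pushforward, _ref_coords_of
from .timestepping import BDFScheme, NewtonConfig, time_loop

__all__ = [
    "pushforward_basis",
    "ReducedSubdomain",
    "ReducedSystem",
    "build_reduced_system",
    "build_convective_tensor",
    "reduced_solve",
    "reconstruct",
    "broken_norm_errors",
    "ErrorReport",
]


def pushforward_basis(archive_basis: np.ndarray, gmap, ref_coords: np.ndarray) -> np.ndarray:
    """Piola-push every column of a reference velocity basis onto the
    deformed subdomain (free-DOF to free-DOF)."""
    out = np.empty_like(archive_basis)
    for c in range(archive_basis.shape[1]):
        col = archive_basis[:, c]
        v_hat = np.column_stack([col[0::2], col[1::2]])
        v = piola_pushforward(gmap, ref_coords, v_hat)
        out[0::2, c] = v[:, 0]
        out[1::2, c] = v[:, 1]
    return out


@dataclass
class ReducedSubdomain:
    """Projected operators of one subdomain."""

    V_u: np.ndarray  # (n_uf, N_u) pushforward basis
    V_p: np.ndarray  # (n_p, N_p)
    M: np.ndarray
    K: np.ndarray
    D: np.ndarray  # (N_p, N_u)
    blockop: object  # the underlying SubdomainOperators (for C assembly)
    tensor: np.ndarray | None = None  # (N_u, N_c, N_c)

    @property
    def n_u(self) -> int:
        return self.V_u.shape[1]

    @property
    def n_p(self) -> int:
        return self.V_p.shape[1]

    @property
    def n_w(self) -> int:
        return self.n_u + self.n_p

    def convective_residual(self, u_red: np.ndarray, use_tensor: bool) -> np.ndarray:
        """c^N(u) = V^T C(V u) V u, by tensor contraction or direct projection."""
        if use_tensor:
            if self.tensor is None or self.tensor.shape[1] == 0:
                return np.zeros(self.n_u)
            nc = self.tensor.shape[1]
            return np.einsum("ilm,l,m->i", self.tensor, u_red[:nc], u_red[:nc])
        u_full = self.V_u @ u_red
        C = self.blockop.C_ff(u_full)
        return self.V_u.T @ (C @ u_full)

    def convective_jacobian(self, u_red: np.ndarray) -> np.ndarray:
        u_full = self.V_u @ u_red
        C = self.blockop.C_ff(u_full) + self.blockop.C2_ff(u_full)
        return self.V_u.T @ (C @ self.V_u)


def build_convective_tensor(rsub: ReducedSubdomain, n_c: int) -> np.ndarray:
    """T[i, l, m] = zeta_i^T C(zeta_m) zeta_l for l, m < n_c (all i)."""
    if not 0 <= n_c <= rsub.n_u:
        raise ValueError("truncation size must lie in [0, basis size]")
    N = rsub.n_u
    T = np.zeros((N, n_c, n_c))
    for m in range(n_c):
        Cm = rsub.blockop.C_ff(rsub.V_u[:, m])
        T[:, :, m] = rsub.V_u.T @ (Cm @ rsub.V_u[:, :n_c])
    return T


@dataclass
class ReducedSystem:
    """Reduced coupled system; satisfies the time-loop system contract."""

    fom: GlobalSystem
    subs: list  # ReducedSubdomain per subdomain
    B_red: np.ndarray  # (n_Lambda, n_W_red) dense (multipliers not reduced)
    use_tensor: bool = False
    _H: sp.csr_matrix = field(default=None, repr=False)

    @property
    def w_offsets(self):
        off = [0]
        for s in self.subs:
            off.append(off[-1] + s.n_w)
        return off

    @property
    def n_W(self) -> int:
        return self.w_offsets[-1]

    @property
    def n_Lambda(self) -> int:
        return self.fom.n_Lambda

    @property
    def n_Y(self) -> int:
        return self.n_W + self.n_Lambda

    def subdomain_state(self, Y, j):
        off = self.w_offsets
        w = Y[off[j]: off[j + 1]]
        return w[: self.subs[j].n_u], w[self.subs[j].n_u:]

    def H_matrix(self) -> sp.csr_matrix:
        if self._H is None:
            blocks = []
            for s in self.subs:
                Hj = np.zeros((s.n_w, s.n_w))
                Hj[: s.n_u, : s.n_u] = s.M
                blocks.append(Hj)
            HW = sla.block_diag(*blocks)
            n = self.n_Y
            H = np.zeros((n, n))
            H[: self.n_W, : self.n_W] = HW
            self._H = sp.csr_matrix(H)
        return self._H

    def _steady_blocks(self, W, newton: bool, frozen: bool):
        out = []
        off = self.w_offsets
        for j, s in enumerate(self.subs):
            A = s.K.copy()
            if not frozen:
                u = W[off[j]: off[j] + s.n_u]
                A = A + (s.convective_jacobian(u) if newton else
                         self._conv_matrix(s, u))
            blk = np.zeros((s.n_w, s.n_w))
            blk[: s.n_u, : s.n_u] = A
            blk[: s.n_u, s.n_u:] = s.D.T
            blk[s.n_u:, : s.n_u] = s.D
            out.append(blk)
        return out

    @staticmethod
    def _conv_matrix(s: ReducedSubdomain, u):
        u_full = s.V_u @ u
        return s.V_u.T @ (s.blockop.C_ff(u_full) @ s.V_u)

    def steady_matrix(self, W, newton: bool = False, frozen: bool = False) -> sp.csr_matrix:
        A = sla.block_diag(*self._steady_blocks(W, newton, frozen))
        top = np.hstack([A, self.B_red.T])
        bot = np.hstack([self.B_red, np.zeros((self.n_Lambda, self.n_Lambda))])
        return sp.csr_matrix(np.vstack([top, bot]))

    def F0(self, t: float, Y: np.ndarray) -> np.ndarray:
        W, Lam = Y[: self.n_W], Y[self.n_W:]
        out = np.zeros(self.n_Y)
        out[self.n_W:] = self.fom.G_vector(t) - self.B_red @ W
        off = self.w_offsets
        lin = np.zeros(self.n_W)
        for j, s in enumerate(self.subs):
            u, p = self.subdomain_state(Y, j)
            sl = slice(off[j], off[j + 1])
            r_u = s.K @ u + s.D.T @ p + s.convective_residual(u, self.use_tensor)
            r_p = s.D @ u
            lin[sl] = np.concatenate([r_u, r_p])
        out[: self.n_W] = -(lin + self.B_red.T @ Lam)
        return out

    def frozen_solver(self, scheme: BDFScheme):
        """Prefactorized solve of the frozen tangent via the reduced Schur
        decomposition over the multipliers (factorized once)."""
        s_fac = scheme.dt * scheme.beta
        blocks = self._steady_blocks(np.zeros(self.n_W), newton=False, frozen=True)
        off = self.w_offsets
        lus = []
        for j, blk in enumerate(blocks):
            Aj = np.zeros_like(blk)
            sH = self.subs[j]
            Aj[: sH.n_u, : sH.n_u] = sH.M
            lus.append(sla.lu_factor(Aj + s_fac * blk))
        Bt = s_fac * self.B_red
        nL = self.n_Lambda
        S = np.zeros((nL, nL))
        for j in range(len(self.subs)):
            sl = slice(off[j], off[j + 1])
            Bj = Bt[:, sl]
            if not Bj.any():
                continue
            Z = sla.lu_solve(lus[j], Bj.T)
            S -= Bj @ Z
        S_lu = sla.lu_factor(S)

        def apply_A_inv(r):
            out = np.empty_like(r)
            for j in range(len(self.subs)):
                sl = slice(off[j], off[j + 1])
                out[sl] = sla.lu_solve(lus[j], r[sl])
            return out

        def solve(rhs):
            B_w, B_l = rhs[: self.n_W], rhs[self.n_W:]
            Z_w = apply_A_inv(B_w)
            X_l = sla.lu_solve(S_lu, B_l - Bt @ Z_w)
            X_w = Z_w - apply_A_inv(Bt.T @ X_l)
            return np.concatenate([X_w, X_l])

        return solve


def build_reduced_system(fom: GlobalSystem, archive: BasisArchive,
                         n_c: int | None = None, use_tensor: bool = False) -> ReducedSystem:
    """Project the assembled FOM onto the archive bases.

    ``n_c``: truncation size for the convective tensor (None = full basis
    size when ``use_tensor`` is set).
    """
    subs = []
    for j, b in enumerate(fom.blocks):
        kind = b.subdomain.kind
        bb = archive.blocks[kind]
        ref_coords = _ref_coords_of(b)
        V_u = pushforward_basis(bb.V_u, b.subdomain.map, ref_coords)
        V_p = bb.V_p
        M = V_u.T @ (b.M_ff() @ V_u)
        K = V_u.T @ (b.K_ff() @ V_u)
        D = V_p.T @ (b.D_f() @ V_u)
        subs.append(ReducedSubdomain(V_u, V_p, M, K, D, b))

    nl = fom.basis.n_lambda
    n_W_red = sum(s.n_w for s in subs)
    B_red = np.zeros((fom.n_Lambda, n_W_red))
    off = [0]
    for s in subs:
        off.append(off[-1] + s.n_w)
    for gi, group in enumerate(fom.B_rows):
        for j, Bju in group.items():
            B_red[gi * nl:(gi + 1) * nl, off[j]: off[j] + subs[j].n_u] = \
                np.asarray((Bju @ subs[j].V_u))
    rsys = ReducedSystem(fom, subs, B_red, use_tensor=use_tensor)
    if use_tensor:
        for s in subs:
            s.tensor = build_convective_tensor(s, s.n_u if n_c is None else min(n_c, s.n_u))
    return rsys


def reduced_solve(rsys: ReducedSystem, scheme: BDFScheme, t_start: float, t_end: float,
                  newton: NewtonConfig | None = None):
    """March the reduced system with the frozen tangent (factorized once)."""
    newton = newton or NewtonConfig(exact_tangent=False)
    solver = rsys.frozen_solver(scheme) if not newton.exact_tangent else None
    return time_loop(rsys, scheme, t_start, t_end, newton=newton,
                     frozen_tangent_solver=solver)


def reconstruct(rsys: ReducedSystem, Y: np.ndarray):
    """FE free-DOF fields per subdomain: list of (u_free, p)."""
    out = []
    for j, s in enumerate(rsys.subs):
        u, p = rsys.subdomain_state(Y, j)
        out.append((s.V_u @ u, s.V_p @ p))
    return out


@dataclass
class ErrorReport:
    e_u: float
    e_p: float
    u_traces: np.ndarray  # per-timestep broken-norm of the FOM solution
    p_traces: np.ndarray
    u_err_traces: np.ndarray
    p_err_traces: np.ndarray


def broken_norm_errors(fom: GlobalSystem, fom_states: np.ndarray,
                       rsys: ReducedSystem, rom_states: np.ndarray,
                       times: np.ndarray) -> ErrorReport:
    """Time-integrated relative broken-norm errors

    e_u^2 = int ||u_h - u_N||_{b,V}^2 / int ||u_h||_{b,V}^2   (H^1 broken),
    e_p^2 analogously in the L^2 broken norm, trapezoidal in time.
    """
    if fom_states.shape[0] != rom_states.shape[0]:
        raise ValueError("trajectories have different lengths")
    nt = fom_states.shape[0]
    ue2 = np.zeros(nt)
    un2 = np.zeros(nt)
    pe2 = np.zeros(nt)
    pn2 = np.zeros(nt)
    Xus = [b.ops.X_u[np.ix_(b.free, b.free)] for b in fom.blocks]
    Xps = [b.ops.X_p for b in fom.blocks]
    for k in range(nt):
        rec = reconstruct(rsys, rom_states[k])
        for j, b in enumerate(fom.blocks):
            u_h, p_h = fom.subdomain_state(fom_states[k], j)
            u_N, p_N = rec[j]
            du, dp = u_h - u_N, p_h - p_N
            ue2[k] += du @ (Xus[j] @ du)
            un2[k] += u_h @ (Xus[j] @ u_h)
            pe2[k] += dp @ (Xps[j] @ dp)
            pn2[k] += p_h @ (Xps[j] @ p_h)
    e_u = np.sqrt(np.trapezoid(ue2, times) / max(np.trapezoid(un2, times), 1e-300))
    e_p = np.sqrt(np.trapezoid(pe2, times) / max(np.trapezoid(pn2, times), 1e-300))
    return ErrorReport(float(e_u), float(e_p), np.sqrt(un2), np.sqrt(pn2),
                       np.sqrt(ue2), np.sqrt(pe2))
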