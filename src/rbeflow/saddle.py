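"""Block preconditioning of the coupled tangent system.

The Newton tangent has the 2x2 saddle form

    [[A~, B~^T], [B~, 0]],     A~ = H + dt*beta*A  (block diagonal over
                               subdomains), B~ = dt*beta*B,

whose exact block-LDU decomposition gives the solve recipe

    Z_w     = A~^{-1} B_w
    X_lam   = S^{-1} (B_lam - B~ Z_w),     S = -B~ A~^{-1} B~^T
    X_w     = Z_w - A~^{-1} B~^T X_lam.

S is small (total multiplier count squared): it is assembled column by
column by applying the per-subdomain (approximate) inverse to the columns
of B~^T, stored dense and factorized.  The local inverse policy is

* ``lu``      exact sparse factorization (the preconditioner is then the
              exact system inverse and any Krylov method converges in one
              application);
* ``simple``  one SIMPLE sweep (diagonal-of-F pressure Schur complement);
* ``gmres``   an inner GMRES solve with a loose tolerance.

With inner iterative solves the outer method must be *flexible* GMRES,
which is what :func:`krylov_solve` uses throughout.  The Schur complement
may be reused across several preconditioner applications (``n_reuse``)
without noticeably degrading the outer iteration counts.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["SimpleLocalInverse", "BlockPreconditioner", "fgmres", "krylov_solve"]


class SimpleLocalInverse:
    """One SIMPLE sweep as an approximate inverse of a local saddle block
    [[F, G], [D, 0]] (velocity-pressure sizes n_u, n_p).

    The pressure Schur complement is built from the inverted diagonal of F:
    S_p = -D diag(F)^{-1} G; the sweep is a predictor solve with F, a
    pressure solve with S_p and a diag(F)-based velocity correction.
    """

    def __init__(self, F: sp.spmatrix, G: sp.spmatrix, D: sp.spmatrix):
        self.n_u = F.shape[0]
        self.n_p = D.shape[0] if D is not None else 0
        dF = np.asarray(F.diagonal())
        if np.any(dF == 0.0):
            raise ValueError("zero diagonal entry in the momentum block")
        self.dF_inv = 1.0 / dF
        self.F_lu = spla.splu(F.tocsc())
        self.G = G.tocsr() if G is not None else None
        self.D = D.tocsr() if D is not None else None
        if self.n_p:
            Sp = -(self.D @ sp.diags(self.dF_inv) @ self.G)
            self.Sp_lu = spla.splu(Sp.tocsc())

    def __call__(self, b: np.ndarray) -> np.ndarray:
        bu, bp = b[: self.n_u], b[self.n_u:]
        u_star = self.F_lu.solve(bu)
        if not self.n_p:
            return u_star
        p = self.Sp_lu.solve(bp - self.D @ u_star)
        u = u_star - self.dF_inv * (self.G @ p)
        return np.concatenate([u, p])


def _make_local_inverse(block: sp.spmatrix, policy, split=None):
    """Return a callable rhs -> approximate solution for one diagonal block.

    ``policy``: 'lu' | 'simple' | ('gmres', tol).  ``split`` gives
    (n_u, n_p) for the SIMPLE policy.
    """
    if policy == "lu":
        lu = spla.splu(block.tocsc())
        return lu.solve
    if policy == "simple":
        if split is None:
            raise ValueError("SIMPLE policy needs the (n_u, n_p) split")
        n_u, n_p = split
        A = block.tocsr()
        F = A[:n_u, :n_u]
        G = A[:n_u, n_u:] if n_p else None
        D = A[n_u:, :n_u] if n_p else None
        return SimpleLocalInverse(F, G, D)
    if isinstance(policy, tuple) and policy[0] == "gmres":
        tol = policy[1]
        A = block.tocsc()
        ilu = spla.spilu(A, drop_tol=1e-4, fill_factor=10)

        def solve(rhs, A=A, ilu=ilu, tol=tol):
            M = spla.LinearOperator(A.shape, ilu.solve)
            x, _ = spla.gmres(A, rhs, rtol=tol, atol=0.0, maxiter=200, M=M)
            return x

        return solve
    raise ValueError(f"unknown local solver policy {policy!r}")


class BlockPreconditioner:
    """Schur-complement preconditioner over the multiplier space."""

    def __init__(self, A_blocks, B_tilde: sp.spmatrix, policy="lu",
                 splits=None, n_reuse: int = 20):
        self.offsets = np.concatenate([[0], np.cumsum([b.shape[0] for b in A_blocks])])
        self.n_W = int(self.offsets[-1])
        self.B = B_tilde.tocsc()
        self.n_L = self.B.shape[0]
        self.policy = policy
        self.splits = splits or [None] * len(A_blocks)
        self.n_reuse = max(1, int(n_reuse))
        self._applications_since_schur = 0
        self.S_lu = None
        self.set_blocks(A_blocks)

    def set_blocks(self, A_blocks):
        """Install (new) diagonal blocks; the Schur complement is refreshed
        lazily once the reuse budget is exhausted."""
        self.local_inv = [
            _make_local_inverse(blk, self.policy, spl)
            for blk, spl in zip(A_blocks, self.splits)
        ]

    def _apply_A_inv(self, r: np.ndarray) -> np.ndarray:
        out = np.empty_like(r)
        for k, inv in enumerate(self.local_inv):
            sl = slice(self.offsets[k], self.offsets[k + 1])
            out[sl] = inv(r[sl])
        return out

    def assemble_schur(self) -> np.ndarray:
        """S = -B~ A~^{-1} B~^T, built by block-local solves."""
        S = np.zeros((self.n_L, self.n_L))
        Bt = self.B.T.tocsr()
        for k, inv in enumerate(self.local_inv):
            sl = slice(self.offsets[k], self.offsets[k + 1])
            Bk = self.B[:, sl]
            if Bk.nnz == 0:
                continue
            Btk = np.asarray(Bt[sl].todense())
            Z = np.column_stack([inv(Btk[:, c]) for c in range(self.n_L)])
            S -= Bk @ Z
        return S

    def refresh_schur(self):
        self.S_lu = sla.lu_factor(self.assemble_schur())
        self._applications_since_schur = 0

    def apply(self, r: np.ndarray) -> np.ndarray:
        """Two-solve application of the decomposition (exact when the local
        policy is 'lu' and the Schur complement is fresh)."""
        if self.S_lu is None or self._applications_since_schur >= self.n_reuse:
            self.refresh_schur()
        self._applications_since_schur += 1
        B_w, B_l = r[: self.n_W], r[self.n_W:]
        Z_w = self._apply_A_inv(B_w)
        X_l = sla.lu_solve(self.S_lu, B_l - self.B @ Z_w) if self.n_L else B_l
        X_w = Z_w - self._apply_A_inv(self.B.T @ X_l) if self.n_L else Z_w
        return np.concatenate([X_w, X_l])

    @classmethod
    def from_system(cls, system, scheme, Y: np.ndarray, policy="simple",
                    newton: bool = False, frozen: bool = False, n_reuse: int = 20):
        """Build from a GlobalSystem and a BDF scheme at state Y."""
        s = scheme.dt * scheme.beta
        W = Y[: system.n_W]
        blocks, splits = [], []
        off = system.w_offsets
        for j, b in enumerate(system.blocks):
            u = None if frozen else W[off[j]: off[j] + b.n_uf]
            blk = b.mass_block() + s * b.saddle_block(u, newton=newton)
            blocks.append(blk.tocsr())
            splits.append((b.n_uf, b.n_p))
        B_tilde = s * system.B_matrix()
        return cls(blocks, B_tilde, policy=policy, splits=splits, n_reuse=n_reuse)


def fgmres(matvec, b: np.ndarray, precond=None, tol: float = 1e-8,
           restart: int = 100, maxiter: int = 500, x0=None):
    """Right-preconditioned flexible GMRES.

    ``matvec(x)`` applies the operator, ``precond(r)`` the (possibly
    nonlinear/varying) preconditioner.  Returns (x, total_iterations);
    raises RuntimeError if the relative residual target is not met.
    """
    n = b.shape[0]
    if precond is None:
        precond = lambda r: r
    x = np.zeros(n) if x0 is None else x0.copy()
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return x, 0
    total = 0
    for _outer in range(max(1, maxiter // restart + 1)):
        r = b - matvec(x)
        beta = np.linalg.norm(r)
        if beta / bnorm <= tol:
            return x, total
        m = restart
        V = np.zeros((n, m + 1))
        Z = np.zeros((n, m))
        Hh = np.zeros((m + 1, m))
        V[:, 0] = r / beta
        g = np.zeros(m + 1)
        g[0] = beta
        cs, sn = np.zeros(m), np.zeros(m)
        k_used = 0
        for k in range(m):
            Z[:, k] = precond(V[:, k])
            w = matvec(Z[:, k])
            for i in range(k + 1):
                Hh[i, k] = w @ V[:, i]
                w = w - Hh[i, k] * V[:, i]
            Hh[k + 1, k] = np.linalg.norm(w)
            if Hh[k + 1, k] > 1e-300:
                V[:, k + 1] = w / Hh[k + 1, k]
            # Givens rotations
            for i in range(k):
                t = cs[i] * Hh[i, k] + sn[i] * Hh[i + 1, k]
                Hh[i + 1, k] = -sn[i] * Hh[i, k] + cs[i] * Hh[i + 1, k]
                Hh[i, k] = t
            denom = np.hypot(Hh[k, k], Hh[k + 1, k])
            cs[k], sn[k] = Hh[k, k] / denom, Hh[k + 1, k] / denom
            Hh[k, k] = denom
            Hh[k + 1, k] = 0.0
            g[k + 1] = -sn[k] * g[k]
            g[k] = cs[k] * g[k]
            total += 1
            k_used = k + 1
            if abs(g[k + 1]) / bnorm <= tol or total >= maxiter:
                break
        y = sla.solve_triangular(Hh[:k_used, :k_used], g[:k_used])
        x = x + Z[:, :k_used] @ y
        if abs(g[k_used]) / bnorm <= tol:
            return x, total
        if total >= maxiter:
            break
    r = b - matvec(x)
    if np.linalg.norm(r) / bnorm <= tol:
        return x, total
    raise RuntimeError(f"FGMRES did not converge in {total} iterations")


def krylov_solve(operator, precond, rhs: np.ndarray, tol: float = 1e-8,
                 restart: int = 100, maxiter: int = 500):
    """Solve operator x = rhs with flexible GMRES and the block
    preconditioner (or any callable / None)."""
    matvec = operator.dot if hasattr(operator, "dot") else operator
    M = precond.apply if isinstance(precond, BlockPreconditioner) else precond
    return fgmres(matvec, rhs, M, tol=tol, restart=restart, maxiter=maxiter)
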