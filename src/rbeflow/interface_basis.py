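"""Spectral Lagrange-multiplier basis on reference interfaces.

Velocity continuity across subdomain interfaces and inlet Dirichlet data are
enforced weakly against a small set of vector-valued spectral functions.  In
3D the reference interface is the closed unit disk and the scalar modes are
ridge polynomials built from Chebyshev polynomials of the second kind,

    P_k^n(x, y) = U_n(x cos w + y sin w),   w = k*pi/(n+1),  0 <= k <= n,

which are orthonormal on the disk with respect to the constant weight
W = 1/pi.  In 2D the reference interface is the interval [-1, 1] and the
scalar modes are the U_n themselves, orthonormal under the half-circle
weight (2/pi)*sqrt(1 - x^2).  The vector basis is the tensor set
{scalar mode} x {canonic vector}, giving

    N_lambda = d (n+1)(n+2)/2   (d = 3),      N_lambda = d (n+1)   (d = 2).

Each physical interface (a circle in 3D, a segment in 2D) carries an affine
map Theta from the reference interface; the physical multiplier functions
are c * xi_hat o Theta^{-1} with an orientation sign c = +-1 so that the two
sides of an interface use opposite multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "chebyshev_U",
    "ridge_polynomial",
    "InterfaceBasis",
    "build_basis_set",
    "InterfaceMap",
    "map_to_interface",
    "disk_quadrature",
    "interval_quadrature",
]


def chebyshev_U(n: int, x):
    """Chebyshev polynomial of the second kind, U_n(x), by the recurrence
    U_0 = 1, U_1 = 2x, U_{n+1} = 2x U_n - U_{n-1}.  Vectorized in ``x``."""
    if n < 0:
        raise ValueError("degree must be nonnegative")
    x = np.asarray(x, dtype=float)
    u_prev = np.ones_like(x)
    if n == 0:
        return u_prev
    u = 2.0 * x
    for _ in range(n - 1):
        u_prev, u = u, 2.0 * x * u - u_prev
    return u


def ridge_angle(n: int, k: int) -> float:
    """Direction angle w = k*pi/(n+1) of the ridge polynomial P_k^n."""
    if not 0 <= k <= n:
        raise ValueError(f"index k={k} out of range for degree n={n}")
    return k * np.pi / (n + 1)


def ridge_polynomial(n: int, k: int, x, y):
    """Scalar ridge polynomial P_k^n(x, y) = U_n(x cos w + y sin w) on the
    unit disk.  P_0^0 is constant; the family is orthonormal under W = 1/pi."""
    w = ridge_angle(n, k)
    return chebyshev_U(n, np.asarray(x) * np.cos(w) + np.asarray(y) * np.sin(w))


def disk_quadrature(order: int):
    """Tensorized Gauss–Legendre rule on the unit disk.

    ``order`` points in the radial and angular directions each; exact for
    polynomials of total degree <= 2*order - 2 (radial) by construction.
    Returns (points (m, 2), weights (m,)); weights sum to pi.
    """
    tr, wr = np.polynomial.legendre.leggauss(order)
    r = 0.5 * (tr + 1.0)  # [0, 1]
    wr = 0.5 * wr
    th = np.pi * (np.arange(2 * order + 1) * 2 + 1) / (2 * order + 1)  # trapezoidal in angle
    # periodic trapezoid is exact for trig polynomials of degree <= 2*order
    wth = np.full(th.size, 2 * np.pi / th.size)
    R, TH = np.meshgrid(r, th, indexing="ij")
    WR, WTH = np.meshgrid(wr, wth, indexing="ij")
    pts = np.column_stack([(R * np.cos(TH)).ravel(), (R * np.sin(TH)).ravel()])
    wts = (WR * WTH * R).ravel()
    return pts, wts


def interval_quadrature(order: int):
    """Gauss–Legendre rule on [-1, 1]; returns (points (m, 1), weights)."""
    t, w = np.polynomial.legendre.leggauss(order)
    return t[:, None], w


@dataclass
class InterfaceBasis:
    """Vector-valued multiplier basis on the reference interface.

    Ordering is component-major: all scalar modes times e_1, then times e_2
    (and e_3 in 3D); within a component, modes are degree-major
    (n~ = 0..n, k = 0..n~).  This ordering is fixed so that coupling
    matrices are bitwise reproducible.
    """

    d: int
    n: int
    mode_index: list = field(repr=False)  # list of (n~, k) per scalar mode
    quad_points: np.ndarray = field(repr=False)
    quad_weights: np.ndarray = field(repr=False)

    @property
    def n_scalar(self) -> int:
        return len(self.mode_index)

    @property
    def n_lambda(self) -> int:
        return self.d * self.n_scalar

    def eval_scalar(self, points: np.ndarray) -> np.ndarray:
        """Evaluate all scalar modes at reference points (m, d-1).

        Returns an array (n_scalar, m)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty((self.n_scalar, pts.shape[0]))
        for i, (nn, k) in enumerate(self.mode_index):
            if self.d == 3:
                out[i] = ridge_polynomial(nn, k, pts[:, 0], pts[:, 1])
            else:
                # normalized U_n under weight (2/pi) sqrt(1-x^2)
                out[i] = chebyshev_U(nn, pts[:, 0])
        return out

    def weight(self, points: np.ndarray) -> np.ndarray:
        """Orthonormality weight W at reference points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.d == 3:
            return np.full(pts.shape[0], 1.0 / np.pi)
        return (2.0 / np.pi) * np.sqrt(np.clip(1.0 - pts[:, 0] ** 2, 0.0, None))

    def eval_vector(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the full vector basis at reference points.

        Returns (n_lambda, m, d): basis function i, point, component."""
        scal = self.eval_scalar(points)
        m = scal.shape[1]
        out = np.zeros((self.n_lambda, m, self.d))
        for c in range(self.d):
            out[c * self.n_scalar:(c + 1) * self.n_scalar, :, c] = scal
        return out

    def gram(self) -> np.ndarray:
        """Numerical Gram matrix of the scalar modes under the weight W."""
        if self.d == 3:
            pts, wts = self.quad_points, self.quad_weights
            w = self.weight(pts) * wts
        else:
            # Gauss–Jacobi absorbs the sqrt(1-x^2) part of the weight exactly
            from scipy.special import roots_jacobi

            x, wj = roots_jacobi(2 * self.n + 4, 0.5, 0.5)
            pts = x[:, None]
            w = (2.0 / np.pi) * wj
        phi = self.eval_scalar(pts)
        return phi @ (phi * w).T


def build_basis_set(d: int, n: int) -> InterfaceBasis:
    """Build the multiplier basis for ambient dimension ``d`` and maximum
    degree ``n``; the count is d(n+1)(n+2)/2 in 3D and d(n+1) in 2D."""
    if d not in (2, 3):
        raise ValueError(f"unsupported ambient dimension d={d}")
    if n < 0:
        raise ValueError("maximum degree must be nonnegative")
    if d == 3:
        modes = [(nn, k) for nn in range(n + 1) for k in range(nn + 1)]
        qp, qw = disk_quadrature(max(2 * n + 2, 4))
    else:
        modes = [(nn, 0) for nn in range(n + 1)]
        qp, qw = interval_quadrature(max(2 * n + 2, 4))
    return InterfaceBasis(d=d, n=n, mode_index=modes, quad_points=qp, quad_weights=qw)


@dataclass
class InterfaceMap:
    """Affine map Theta from the reference interface onto a physical one.

    2D: Theta(s) = center + s * halfwidth * tangent, s in [-1, 1].  The
    in-plane frame is fixed deterministically from the stored interface
    normal (tangent = normal rotated by +pi/2), so multiplier coefficients
    are reproducible.  ``sign`` is the orientation c = +-1 of this side.
    """

    center: np.ndarray
    normal: np.ndarray
    radius: float  # half-width in 2D
    sign: int = 1

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        nrm = np.asarray(self.normal, dtype=float)
        self.normal = nrm / np.linalg.norm(nrm)
        if self.radius <= 0:
            raise ValueError("degenerate interface: nonpositive radius")
        # deterministic tangent: rotate the normal by +90 degrees
        self.tangent = np.array([-self.normal[1], self.normal[0]])

    @property
    def measure(self) -> float:
        """Length of the physical interface (2D)."""
        return 2.0 * self.radius

    def forward(self, s) -> np.ndarray:
        """Map reference coordinates s (m,) or (m,1) to physical points."""
        s = np.atleast_1d(np.asarray(s, dtype=float)).reshape(-1)
        return self.center[None, :] + s[:, None] * self.radius * self.tangent[None, :]

    def inverse(self, x: np.ndarray) -> np.ndarray:
        """Map physical points (m, 2) to reference coordinates (m,)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.center[None, :]) @ self.tangent / self.radius


def map_to_interface(basis: InterfaceBasis, iface: InterfaceMap):
    """Return an evaluator of the mapped multiplier basis.

    The returned callable takes physical points (m, d) and gives
    (n_lambda, m, d) values of c * xi_hat o Theta^{-1}; the vector
    components are carried in the interface frame (component 1 along the
    interface normal, component 2 along the tangent), the same on both
    sides of an interface so that sign flipping realizes xi^- = -xi^+.
    """
    if basis.d != 2:
        raise NotImplementedError("physical interface mapping is 2D here")
    frame = np.stack([iface.normal, iface.tangent])  # (d, d): rows are axes

    def evaluate(x: np.ndarray) -> np.ndarray:
        s = iface.inverse(x)
        vals = basis.eval_vector(s[:, None])  # components in reference axes
        # rotate e_1 -> normal, e_2 -> tangent
        out = np.einsum("imc,cd->imd", vals, frame)
        return iface.sign * out

    return evaluate
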