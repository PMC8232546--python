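"""BDF time discretization and Newton–Raphson solution of the global system.

At each step the state Y_{k+1} solves

    R(Y_{k+1}) = H Y_{k+1} - sum_j alpha_j H Y_{k-j+1} - dt beta F0(t_{k+1}, Y_{k+1}) = 0,

where H is the (singular) block mass and F0 collects forcing, boundary data
and the steady operator.  Supported orders: sigma = 1 (backward Euler,
alpha = [1], beta = 1) and sigma = 2 (alpha = [4/3, -1/3], beta = 2/3).
The Newton tangent is H + dt beta [[A'(W), B^T], [B, 0]]; with the exact
convective derivative the iteration is quadratic, with the frozen Stokes
operator it is linear but the tangent is constant in time.

The ``system`` object only needs ``H_matrix()``, ``F0(t, Y)`` and
``steady_matrix(W, newton=..., frozen=...)`` — the coupled FE system and
the reduced system both satisfy this contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "bdf_coefficients",
    "BDFScheme",
    "NewtonConfig",
    "InflowSpec",
    "ramp_flow",
    "newton_solve",
    "time_loop",
]


def bdf_coefficients(sigma: int):
    """(alpha list, beta) of the BDF scheme of order ``sigma``."""
    if sigma == 1:
        alpha, beta = [1.0], 1.0
    elif sigma == 2:
        alpha, beta = [4.0 / 3.0, -1.0 / 3.0], 2.0 / 3.0
    else:
        raise ValueError(f"unsupported BDF order {sigma}")
    assert abs(sum(alpha) - 1.0) < 1e-14, "BDF consistency requires sum(alpha) = 1"
    return alpha, beta


@dataclass
class BDFScheme:
    sigma: int
    dt: float

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("timestep must be positive")
        self.alpha, self.beta = bdf_coefficients(self.sigma)


@dataclass
class NewtonConfig:
    tol: float = 1e-6  # relative residual tolerance
    atol: float = 1e-12  # absolute floor (guards steady states where R ~ 0)
    max_iter: int = 20
    exact_tangent: bool = True  # False: frozen (Stokes) tangent
    divergence_factor: float = 1e4


@dataclass
class InflowSpec:
    """Flow-rate law with cosine start-up ramp.

    Q(t) = Q0 [1 - cos((t - t_ramp) pi / (t0 - t_ramp))] / 2 on the ramp
    interval [t_ramp, t0]; afterwards the (optional) waveform takes over,
    defaulting to the constant Q0.
    """

    Q0: float = 1.0
    t_ramp: float = -2.0e-2
    t0: float = 0.0
    waveform: object = None  # callable t -> Q for t >= t0

    def __call__(self, t: float) -> float:
        if t <= self.t_ramp:
            return 0.0
        if t < self.t0:
            return ramp_flow(self, t)
        if self.waveform is None:
            return self.Q0
        return self.waveform(t)


def ramp_flow(spec: InflowSpec, t: float) -> float:
    """Cosine ramp value; ``t`` must lie in [t_ramp, t0]."""
    if not spec.t_ramp <= t <= spec.t0:
        raise ValueError("time outside the ramp interval")
    tau = (t - spec.t_ramp) * np.pi / (spec.t0 - spec.t_ramp)
    return spec.Q0 * (1.0 - np.cos(tau)) / 2.0


def bdf_residual(system, scheme: BDFScheme, t: float, Y: np.ndarray, history) -> np.ndarray:
    """R(Y) at time t given the history [Y_k, Y_{k-1}, ...]."""
    H = system.H_matrix()
    acc = H @ Y
    for a, Yj in zip(scheme.alpha, history):
        acc = acc - a * (H @ Yj)
    return acc - scheme.dt * scheme.beta * system.F0(t, Y)


def bdf_tangent(system, scheme: BDFScheme, Y: np.ndarray, exact: bool = True) -> sp.csr_matrix:
    n_W = system.n_W
    W = Y[:n_W]
    S = system.steady_matrix(W, newton=exact, frozen=not exact)
    return (system.H_matrix() + scheme.dt * scheme.beta * S).tocsr()


def newton_solve(residual_fn, tangent_fn, Y0: np.ndarray, config: NewtonConfig,
                 linear_solver=None):
    """Newton–Raphson with relative-residual stopping.

    ``linear_solver(J, rhs) -> delta`` defaults to a direct sparse solve;
    ``tangent_fn(Y)`` may return a matrix or a prefactorized solve closure
    (callable rhs -> delta), in which case ``linear_solver`` is bypassed.
    Returns (Y, iterations, converged, residual_history).
    """
    if linear_solver is None:
        linear_solver = lambda J, rhs: spla.spsolve(J.tocsc(), rhs)
    Y = Y0.copy()
    r = residual_fn(Y)
    r0 = np.linalg.norm(r)
    hist = [r0]
    if r0 <= config.atol:
        return Y, 0, True, hist
    bad_steps = 0
    for it in range(1, config.max_iter + 1):
        J = tangent_fn(Y)
        delta = J(-r) if callable(J) else linear_solver(J, -r)
        Y = Y + delta
        r = residual_fn(Y)
        rn = np.linalg.norm(r)
        hist.append(rn)
        if rn / r0 < config.tol or rn <= config.atol:
            return Y, it, True, hist
        if rn > hist[-2]:
            bad_steps += 1
            if rn > config.divergence_factor * r0 or bad_steps > 1:
                return Y, it, False, hist
    return Y, config.max_iter, False, hist


def time_loop(system, scheme: BDFScheme, t_start: float, t_end: float,
              Y0: np.ndarray | None = None, newton: NewtonConfig | None = None,
              linear_solver=None, frozen_tangent_solver=None,
              callback=None):
    """March the system from t_start to t_end.

    BDF2 takes its first step with BDF1 (self-starting).  Returns
    (times, states (n_t, n_Y), diagnostics list of dicts).
    ``frozen_tangent_solver``: optional prefactorized solve closure used for
    every step when the Newton config requests the frozen tangent.
    """
    newton = newton or NewtonConfig()
    n_steps = int(round((t_end - t_start) / scheme.dt))
    Y = np.zeros(system.n_Y) if Y0 is None else Y0.copy()
    times = [t_start]
    states = [Y.copy()]
    diags = []
    history = [Y.copy()]
    for k in range(n_steps):
        t = t_start + (k + 1) * scheme.dt
        eff = scheme if len(history) >= scheme.sigma else BDFScheme(1, scheme.dt)
        hist = history[: eff.sigma]

        def residual_fn(Yv, t=t, eff=eff, hist=hist):
            return bdf_residual(system, eff, t, Yv, hist)

        if not newton.exact_tangent and frozen_tangent_solver is not None and eff.sigma == scheme.sigma:
            tangent_fn = lambda Yv: frozen_tangent_solver
        else:
            def tangent_fn(Yv, eff=eff):
                return bdf_tangent(system, eff, Yv, exact=newton.exact_tangent)

        Y, its, ok, rhist = newton_solve(residual_fn, tangent_fn, Y, newton, linear_solver)
        if not ok:
            raise RuntimeError(
                f"Newton failed at step {k + 1} (t = {t:.6g}), residuals {rhist[-3:]}"
            )
        times.append(t)
        states.append(Y.copy())
        diags.append({"t": t, "newton_iterations": its, "residual": rhist[-1]})
        history = [Y.copy()] + history
        history = history[:2]
        if callback is not None:
            callback(k + 1, t, Y)
    return np.array(times), np.array(states), diags
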