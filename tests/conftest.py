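"""Shared fixtures: small geometries, systems and manufactured solutions."""

import numpy as np
import pytest

from rbeflow.coupling import build_global_system
from rbeflow.fem import FluidProperties
from rbeflow.geometry import build_chain
from rbeflow.interface_basis import build_basis_set
from rbeflow.timestepping import InflowSpec


@pytest.fixture(scope="session")
def props():
    return FluidProperties()  # rho = 1.06 g/cm^3, mu = 0.04 g/(cm s)


@pytest.fixture(scope="session")
def basis2d():
    return build_basis_set(2, 5)


@pytest.fixture(scope="session")
def two_tube_system(props, basis2d):
    """Coupled system on a coarse two-tube chain with a short ramp inflow."""
    geo = build_chain(["T1", "T1"], resolution=5)
    inflow = InflowSpec(Q0=1.0, t_ramp=0.0, t0=0.03)
    return build_global_system(geo, basis2d, props, inflow)


@pytest.fixture(scope="session")
def stokes_manufactured():
    """Divergence-free manufactured Stokes solution on the unit square,
    with body force derived symbolically (independent of the assembly)."""
    import sympy as sym

    x, y = sym.symbols("x y")
    mu = sym.Rational(1, 25)
    psi = sym.sin(sym.pi * x) ** 2 * sym.sin(sym.pi * y) ** 2
    u1, u2 = sym.diff(psi, y), -sym.diff(psi, x)
    pex = sym.sin(sym.pi * x) * sym.cos(sym.pi * y)
    f1 = -mu * (sym.diff(u1, x, 2) + sym.diff(u1, y, 2)) + sym.diff(pex, x)
    f2 = -mu * (sym.diff(u2, x, 2) + sym.diff(u2, y, 2)) + sym.diff(pex, y)
    fu = sym.lambdify((x, y), (u1, u2), "numpy")
    fg = sym.lambdify(
        (x, y),
        (sym.diff(u1, x), sym.diff(u1, y), sym.diff(u2, x), sym.diff(u2, y)),
        "numpy",
    )
    fp = sym.lambdify((x, y), pex, "numpy")
    ff = sym.lambdify((x, y), (f1, f2), "numpy")

    def u_exact(P):
        a, b = fu(P[:, 0], P[:, 1])
        return np.column_stack([a, b])

    def grad_exact(P):
        g = fg(P[:, 0], P[:, 1])
        out = np.empty((P.shape[0], 2, 2))
        out[:, 0, 0], out[:, 0, 1], out[:, 1, 0], out[:, 1, 1] = g
        return out

    def p_exact(P):
        return fp(P[:, 0], P[:, 1])

    def force(P):
        a, b = ff(P[:, 0], P[:, 1])
        return np.column_stack([a, b])

    return {"mu": 0.04, "u": u_exact, "grad_u": grad_exact, "p": p_exact, "f": force}
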