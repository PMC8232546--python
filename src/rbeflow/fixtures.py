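"""Small self-contained test assets, generated programmatically."""

from __future__ import annotations

import numpy as np

from .config import (DiscretizationConfig, GeometryConfig, RomConfig,
                     RunConfig, InflowConfig)

__all__ = ["make_fixtures", "two_tube_config", "tree9_config", "saddle_toy"]


def two_tube_config() -> RunConfig:
    """Coarse two-tube chain (< 2000 velocity DOFs in total)."""
    return RunConfig(
        geometry=GeometryConfig(type="chain", kinds=["T1", "T1"], resolution=5),
        discretization=DiscretizationConfig(dt=2.5e-3, t_end=0.05, bdf_order=2,
                                            basis_degree=5),
        inflow=InflowConfig(Q0=1.0, t_ramp=0.0, t0=0.03),
        rom=RomConfig(n_configurations=3),
    )


def tree9_config() -> RunConfig:
    """9-subdomain tree: 4 trunk tubes, a bifurcation, 2 tubes per branch
    (8 internal interfaces, 1 inlet, 2 outlets)."""
    return RunConfig(
        geometry=GeometryConfig(
            type="tree", trunk=["T1", "T2", "T1", "T3"],
            branches=[["T1", "T2"], ["T1", "T2"]], resolution=4,
        ),
        discretization=DiscretizationConfig(dt=2.5e-3, t_end=0.05, bdf_order=2,
                                            basis_degree=5),
        inflow=InflowConfig(Q0=1.0, t_ramp=0.0, t0=0.03),
    )


def saddle_toy(n_u: int = 24, n_p: int = 6, n_l: int = 4, seed: int = 0):
    """A random well-posed saddle system [[A, B^T], [B, 0]] with its dense
    solution for a random right-hand side.

    A is SPD (so the saddle problem is nonsingular for full-rank B); returns
    (A, B, rhs, solution) with the solution computed by a dense solve.
    """
    rng = np.random.default_rng(seed)
    Q = rng.normal(size=(n_u, n_u))
    A = Q @ Q.T + n_u * np.eye(n_u)
    B = rng.normal(size=(n_p + n_l, n_u))
    n = n_u + n_p + n_l
    M = np.zeros((n, n))
    M[:n_u, :n_u] = A
    M[:n_u, n_u:] = B.T
    M[n_u:, :n_u] = B
    rhs = rng.normal(size=n)
    sol = np.linalg.solve(M, rhs)
    return A, B, rhs, sol


def make_fixtures(kind: str, outdir: str | None = None):
    """Build a named fixture; with ``outdir``, write its config file."""
    if kind == "two_tube_2d":
        cfg = two_tube_config()
    elif kind == "tree9":
        cfg = tree9_config()
    elif kind == "saddle_toy":
        return saddle_toy()
    else:
        raise ValueError(f"unknown fixture '{kind}'")
    if outdir is not None:
        import pathlib

        p = pathlib.Path(outdir)
        p.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(p / f"{kind}.yaml")
    return cfg
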