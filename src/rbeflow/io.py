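"""Result export: VTU series, diagnostics tables, multiplier coefficients."""

from __future__ import annotations

import pathlib

import numpy as np

from .fem import wall_shear_stress
from .mesh import write_vtu

__all__ = ["export_state", "write_diagnostics", "write_multipliers"]


def export_state(system, Y: np.ndarray, outdir: str, step: int, with_wss: bool = True):
    """Write one VTU per subdomain with point data 'velocity' (vertex
    values) and 'pressure', plus a text table of wall WSS magnitudes."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for j, b in enumerate(system.blocks):
        u_free, p = system.subdomain_state(Y, j)
        u = b.full_velocity(u_free)
        nv = b.space.mesh.n_points
        vel = np.column_stack([u[0:2 * nv:2], u[1:2 * nv:2]])
        write_vtu(out / f"subdomain{j:02d}_step{step:05d}.vtu", b.space.mesh,
                  point_data={"velocity": vel, "pressure": p})
        if with_wss:
            mids, wss = wall_shear_stress(b.space, b.props, u,
                                          wall_tag=b.subdomain.block.wall_tag)
            tab = np.column_stack([mids, wss])
            np.savetxt(out / f"subdomain{j:02d}_step{step:05d}_wss.txt", tab,
                       header="x y wss", comments="# ")


def write_diagnostics(diags: list, path: str):
    """Per-step diagnostics as a TSV table."""
    keys = sorted({k for d in diags for k in d})
    with open(path, "w") as f:
        f.write("\t".join(keys) + "\n")
        for d in diags:
            f.write("\t".join(f"{d.get(k, '')!r}".strip("'") for k in keys) + "\n")


def write_multipliers(system, Y: np.ndarray, path: str):
    """Multiplier coefficients per interface as tabular text."""
    _, Lam = system.split(Y)
    nl = system.basis.n_lambda
    names = [f"internal_{j}_{m}" for (j, _, m, _, _) in system.geometry.internal]
    names += [f"inlet_{j}_{name}" for (j, name, _) in system.geometry.inlets]
    with open(path, "w") as f:
        f.write("# interface\tmode\tcoefficient\n")
        for g, name in enumerate(names):
            for i in range(nl):
                f.write(f"{name}\t{i}\t{Lam[g * nl + i]:.12g}\n")
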