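"""Offline phase: snapshots, Piola pullback, weighted POD, supremizers.

Snapshots are collected by solving the coupled FE problem on randomly
perturbed variants of a base modular geometry (parameters drawn from
uniform distributions centred on the base values).  Velocity snapshots are
pulled back to the reference building block with the divergence-preserving
Piola transformation

    v_hat(x_hat) = |J_Phi| J_Phi^{-1} v(Phi(x_hat)),

evaluated DOF-wise; pressure snapshots are pulled back by plain composition
(DOF-wise identity).  Per block, a POD orthonormal in the H^1 (velocity) /
L^2 (pressure) norm is computed via the method of snapshots (equivalent to
the Cholesky-SVD construction and cheaper when there are fewer snapshots
than DOFs) and truncated by the relative-information-content criterion

    sum_{i<=N} sigma_i^2 / sum_i sigma_i^2 >= 1 - eps^2.

The velocity space is then enriched with supremizers: solutions of
X_u s = D^T eta for every pressure mode and X_u z = B^T e_l for every
multiplier mode of every interface of the block, which preserve inf-sup
stability of the reduced saddle problem.  The union is re-orthonormalized
against X_u by modified Gram–Schmidt.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .coupling import (SubdomainOperators, assemble_interface_coupling,
                       build_global_system)
from .fem import FluidProperties, assemble_norm_matrices, build_taylor_hood_space
from .geometry import (DeformationParams, GeometricMap, ReferenceBlock,
                       build_reference_block, nonaffine_map)
from .interface_basis import InterfaceBasis, InterfaceMap
from .timestepping import BDFScheme, InflowSpec, NewtonConfig, time_loop

__all__ = [
    "PODConfig",
    "sample_configurations",
    "piola_pullback",
    "piola_pushforward",
    "weighted_pod",
    "pod_truncation_rank",
    "compute_supremizers",
    "finalize_basis",
    "BlockBasis",
    "BasisArchive",
    "SnapshotSet",
    "collect_snapshots",
    "build_archive",
    "run_offline",
]


@dataclass
class PODConfig:
    eps_u: float = 1e-3
    eps_p: float = 1e-4
    n_configurations: int = 5
    halfwidth_ratio: float = 0.10  # +-10% on length/radius ratios
    halfwidth_angle: float = np.deg2rad(10.0)  # +-10 degrees on angles
    seed: int = 0
    snapshot_stride: int = 1
    max_modes: int | None = None

    def __post_init__(self):
        if not (0 < self.eps_u < 1 and 0 < self.eps_p < 1):
            raise ValueError("POD tolerances must lie in (0, 1)")


_ANGLE_KEYS = {"bend_angle", "alpha1", "alpha2"}


def sample_configurations(base_params: list, spec_of, config: PODConfig,
                          rng: np.random.Generator | None = None) -> list:
    """Draw perturbed parameter sets around the base configuration.

    ``base_params`` is a list of DeformationParams (one per subdomain);
    ``spec_of(j)`` returns the admissible-range dict of subdomain j.
    Samples falling outside the admissible range are redrawn (capped).
    Returns a list of lists of DeformationParams.
    """
    rng = rng or np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_configurations):
        cfg = []
        for j, base in enumerate(base_params):
            spec = spec_of(j)
            vals = {}
            for key, v in base.values.items():
                if key not in spec:  # derived quantities (e.g. inherited radii)
                    vals[key] = v
                    continue
                hw = config.halfwidth_angle if key in _ANGLE_KEYS else config.halfwidth_ratio
                lo, hi = spec[key]
                for _attempt in range(100):
                    draw = v + hw * rng.uniform(-1.0, 1.0)
                    if lo <= draw <= hi:
                        break
                else:
                    draw = float(np.clip(v, lo, hi))
                vals[key] = draw
            cfg.append(DeformationParams(vals, base.rotation, base.translation.copy()))
        out.append(cfg)
    return out


def piola_pullback(gmap: GeometricMap, ref_coords: np.ndarray, v_nodes: np.ndarray) -> np.ndarray:
    """Pull a velocity field back to the reference block, DOF-wise.

    ``v_nodes`` has shape (m, 2): values at the deformed images of the
    reference DOF coordinates ``ref_coords``.
    """
    J = gmap.jacobian(ref_coords)
    det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    if np.any(det <= 0):
        raise ValueError("singular or orientation-reversing Jacobian at a DOF")
    v_hat = np.linalg.solve(J, v_nodes[:, :, None])[:, :, 0]
    return det[:, None] * v_hat


def piola_pushforward(gmap: GeometricMap, ref_coords: np.ndarray, v_hat_nodes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`piola_pullback`: v = J v_hat / |J|."""
    J = gmap.jacobian(ref_coords)
    det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    v = np.einsum("mij,mj->mi", J, v_hat_nodes)
    return v / det[:, None]


def pod_truncation_rank(sigma: np.ndarray, eps: float, max_modes: int | None = None) -> int:
    """Smallest N with relative information content >= 1 - eps^2."""
    s2 = sigma**2
    total = s2.sum()
    if total == 0:
        return 0
    content = np.cumsum(s2) / total
    N = int(np.searchsorted(content, 1.0 - eps**2 - 1e-14) + 1)
    N = min(N, sigma.size)
    if max_modes is not None:
        N = min(N, max_modes)
    return N


def weighted_pod(S: np.ndarray, X, eps: float, max_modes: int | None = None):
    """X-orthonormal POD modes of the snapshot matrix S.

    Uses the Gram (method-of-snapshots) path when there are fewer snapshots
    than DOFs, otherwise the Cholesky-SVD construction; the two coincide up
    to sign, which is fixed by making the largest-magnitude entry of every
    mode positive.  Returns (modes (N_h, N), singular values (full))."""
    S = np.asarray(S, dtype=float)
    n_h, n_s = S.shape
    if n_s == 0:
        return np.zeros((n_h, 0)), np.zeros(0)
    if n_s < n_h:
        G = S.T @ (X @ S) if sp.issparse(X) else S.T @ X @ S
        lam, V = np.linalg.eigh(G)
        order = np.argsort(lam)[::-1]
        lam = np.clip(lam[order], 0.0, None)
        V = V[:, order]
        sigma = np.sqrt(lam)
        N = pod_truncation_rank(sigma, eps, max_modes)
        keep = sigma[:N] > max(1e-13 * (sigma[0] if N else 1.0), 1e-300)
        modes = S @ (V[:, :N][:, keep] / sigma[:N][keep])
    else:
        Xd = X.toarray() if sp.issparse(X) else np.asarray(X)
        H = np.linalg.cholesky(Xd).T  # X = H^T H, H upper triangular
        U, sigma, _ = np.linalg.svd(H @ S, full_matrices=False)
        N = pod_truncation_rank(sigma, eps, max_modes)
        modes = np.linalg.solve(H, U[:, :N])
    # deterministic sign convention
    for c in range(modes.shape[1]):
        k = np.argmax(np.abs(modes[:, c]))
        if modes[k, c] < 0:
            modes[:, c] = -modes[:, c]
    return modes, sigma


def compute_supremizers(X_u, D, V_p: np.ndarray, B_list):
    """Pressure and coupling supremizers on one reference block.

    Solves X_u s = D^T eta for every pressure mode eta (columns of V_p) and
    X_u z = B^T e_l for every multiplier mode of every interface coupling
    matrix in ``B_list``.  Returns (S_p (n_u, N_p), S_c (n_u, sum N_lambda)).
    """
    lu = spla.splu(sp.csc_matrix(X_u))
    S_p = np.column_stack([lu.solve(D.T @ V_p[:, k]) for k in range(V_p.shape[1])]) \
        if V_p.shape[1] else np.zeros((X_u.shape[0], 0))
    cols = []
    for B in B_list:
        Bt = np.asarray(B.todense()).T if sp.issparse(B) else np.asarray(B).T
        for l in range(Bt.shape[1]):
            cols.append(lu.solve(Bt[:, l]))
    S_c = np.column_stack(cols) if cols else np.zeros((X_u.shape[0], 0))
    return S_p, S_c


def finalize_basis(modes: np.ndarray, supremizers: np.ndarray, X, drop_tol: float = 1e-8):
    """Concatenate and X-orthonormalize by modified Gram–Schmidt; vectors
    whose X-norm falls below ``drop_tol`` (relative) after projection are
    dropped as linearly dependent."""
    cand = np.column_stack([m for m in (modes, supremizers) if m.size]) \
        if (modes.size or supremizers.size) else np.zeros((X.shape[0], 0))
    if cand.shape[1] == 0:
        raise ValueError("empty basis")
    out = []
    for c in range(cand.shape[1]):
        v = cand[:, c].copy()
        nrm0 = np.sqrt(v @ (X @ v))
        for _pass in range(2):  # re-orthogonalization for stability
            for w in out:
                v = v - (w @ (X @ v)) * w
        nrm = np.sqrt(max(v @ (X @ v), 0.0))
        if nrm > drop_tol * max(nrm0, 1.0):
            out.append(v / nrm)
    return np.column_stack(out)


@dataclass
class BlockBasis:
    """Reduced basis of one reference building block."""

    kind: str
    resolution: int
    V_u: np.ndarray  # (n_free_u, N_u) including supremizers, X_u-orthonormal
    V_p: np.ndarray  # (n_p, N_p), X_p-orthonormal
    sigma_u: np.ndarray
    sigma_p: np.ndarray
    n_pod_u: int
    n_sup_p: int
    n_sup_c: int
    mesh_hash: str = ""


@dataclass
class ReferenceBlockSpace:
    """Reference block with its FE space, norm matrices and free DOFs."""

    block: ReferenceBlock
    space: object
    X_u: sp.spmatrix
    X_p: sp.spmatrix
    free: np.ndarray
    ref_coords_free_nodes: np.ndarray  # coordinates of free velocity DOF nodes

    @classmethod
    def build(cls, kind: str, resolution: int) -> "ReferenceBlockSpace":
        block = build_reference_block(kind, resolution)
        space = build_taylor_hood_space(block.mesh)
        X_u, X_p = assemble_norm_matrices(space)
        wall = space.boundary_dofs(block.wall_tag)
        free = np.setdiff1d(np.arange(space.n_u), wall)
        coords = space.vel_node_coords()
        # free DOFs come in x/y pairs per non-wall node
        free_nodes = free[0::2] // 2
        return cls(block, space, X_u[np.ix_(free, free)], X_p, free, coords[free_nodes])


def _mesh_hash(mesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.points).tobytes())
    h.update(np.ascontiguousarray(mesh.cells).tobytes())
    return h.hexdigest()[:16]


@dataclass
class BasisArchive:
    """Per-block reduced bases plus the metadata needed to reuse them."""

    basis_degree: int
    resolution: int
    blocks: dict  # kind -> BlockBasis
    ref_spaces: dict = field(default_factory=dict)  # kind -> ReferenceBlockSpace
    metadata: dict = field(default_factory=dict)

    def ref_space(self, kind: str) -> ReferenceBlockSpace:
        if kind not in self.ref_spaces:
            self.ref_spaces[kind] = ReferenceBlockSpace.build(kind, self.resolution)
        return self.ref_spaces[kind]

    def save(self, path: str):
        import h5py

        p = pathlib.Path(path)
        p.mkdir(parents=True, exist_ok=True)
        with h5py.File(p / "bases.h5", "w") as f:
            for kind, bb in self.blocks.items():
                g = f.create_group(kind)
                g.create_dataset("V_u", data=bb.V_u)
                g.create_dataset("V_p", data=bb.V_p)
                g.create_dataset("sigma_u", data=bb.sigma_u)
                g.create_dataset("sigma_p", data=bb.sigma_p)
        manifest = {
            "basis_degree": self.basis_degree,
            "resolution": self.resolution,
            "metadata": self.metadata,
            "blocks": {
                k: {
                    "mesh_hash": bb.mesh_hash,
                    "n_pod_u": bb.n_pod_u,
                    "n_sup_p": bb.n_sup_p,
                    "n_sup_c": bb.n_sup_c,
                }
                for k, bb in self.blocks.items()
            },
        }
        (p / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path: str) -> "BasisArchive":
        import h5py

        p = pathlib.Path(path)
        manifest = json.loads((p / "manifest.json").read_text())
        arch = cls(manifest["basis_degree"], manifest["resolution"], {},
                   metadata=manifest.get("metadata", {}))
        with h5py.File(p / "bases.h5", "r") as f:
            for kind, meta in manifest["blocks"].items():
                g = f[kind]
                bb = BlockBasis(
                    kind, arch.resolution, g["V_u"][()], g["V_p"][()],
                    g["sigma_u"][()], g["sigma_p"][()],
                    meta["n_pod_u"], meta["n_sup_p"], meta["n_sup_c"],
                    mesh_hash=meta["mesh_hash"],
                )
                rs = arch.ref_space(kind)
                if _mesh_hash(rs.block.mesh) != bb.mesh_hash:
                    raise ValueError(
                        f"mesh hash mismatch for block '{kind}': archive was built "
                        "on a different reference mesh"
                    )
                arch.blocks[kind] = bb
        return arch


def _reference_couplings(rs: ReferenceBlockSpace, basis: InterfaceBasis):
    """Reference-block coupling matrices B_hat (one per interface, free DOFs)."""
    out = []
    for name, desc in rs.block.interfaces.items():
        imap = InterfaceMap(desc.center, desc.normal, desc.halfwidth, sign=1)
        B = assemble_interface_coupling(rs.space, name, basis, imap)
        out.append(B[:, rs.free])
    return out


@dataclass
class SnapshotSet:
    """Piola-pulled-back per-block snapshot matrices and their provenance."""

    S_u: dict  # kind -> list of free-DOF velocity snapshot vectors
    S_p: dict  # kind -> list of pressure snapshot vectors
    provenance: dict  # kind -> list of (configuration index, step index)
    failures: int = 0


def collect_snapshots(geometry_factory, base_params: list, kinds: list,
                      pod: PODConfig, basis: InterfaceBasis,
                      props: FluidProperties | None = None,
                      scheme: BDFScheme | None = None,
                      inflow: InflowSpec | None = None,
                      t_end: float = 0.1,
                      newton: NewtonConfig | None = None) -> SnapshotSet:
    """Run the coupled FE problem on perturbed configurations and collect
    Piola-pulled-back snapshots per building block.

    Failed configurations (Newton breakdown, inadmissible geometry) are
    skipped and counted.
    """
    props = props or FluidProperties()
    scheme = scheme or BDFScheme(2, 2.5e-3)
    inflow = inflow or InflowSpec(Q0=1.0, t_ramp=0.0, t0=0.05)
    newton = newton or NewtonConfig()
    rng = np.random.default_rng(pod.seed)

    from .geometry import BIF_PARAM_SPEC, TUBE_PARAM_SPEC

    def spec_of(j):
        return BIF_PARAM_SPEC if kinds[j] == "B" else TUBE_PARAM_SPEC

    snaps = SnapshotSet({k: [] for k in set(kinds)}, {k: [] for k in set(kinds)},
                        {k: [] for k in set(kinds)})
    configs = sample_configurations(base_params, spec_of, pod, rng)
    for ci, cfg in enumerate(configs):
        try:
            geo = geometry_factory(cfg)
            system = build_global_system(geo, basis, props, inflow)
            _, states, _ = time_loop(system, scheme, 0.0, t_end, newton=newton)
        except (RuntimeError, ValueError):
            snaps.failures += 1
            continue
        for j, sd in enumerate(geo.subdomains):
            kind = sd.kind
            blockop = system.blocks[j]
            coords = _ref_coords_of(blockop)
            for step in range(1, states.shape[0], pod.snapshot_stride):
                u_free, p_vec = system.subdomain_state(states[step], j)
                v_nodes = _free_to_nodes(blockop, u_free)
                v_hat = piola_pullback(sd.map, coords, v_nodes)
                snaps.S_u[kind].append(_nodes_to_free(blockop, v_hat))
                snaps.S_p[kind].append(p_vec.copy())
                snaps.provenance[kind].append((ci, step))
    return snaps


def build_archive(snaps: SnapshotSet, kinds: list, pod: PODConfig,
                  basis: InterfaceBasis, resolution: int,
                  ref_spaces: dict | None = None) -> BasisArchive:
    """POD + supremizer enrichment per block from collected snapshots."""
    archive = BasisArchive(basis.n, resolution, {},
                           ref_spaces=dict(ref_spaces or {}),
                           metadata={
                               "eps_u": pod.eps_u, "eps_p": pod.eps_p,
                               "seed": pod.seed,
                               "n_configurations": pod.n_configurations,
                               "failures": snaps.failures,
                           })
    for kind in sorted(set(kinds)):
        rs = archive.ref_space(kind)
        Su = np.column_stack(snaps.S_u[kind]) if snaps.S_u[kind] \
            else np.zeros((rs.free.size, 0))
        Sp = np.column_stack(snaps.S_p[kind]) if snaps.S_p[kind] \
            else np.zeros((rs.space.n_p, 0))
        Vu, sig_u = weighted_pod(Su, rs.X_u, pod.eps_u, pod.max_modes)
        Vp, sig_p = weighted_pod(Sp, rs.X_p, pod.eps_p, pod.max_modes)
        D_f = _ref_divergence(rs)
        B_list = _reference_couplings(rs, basis)
        S_p, S_c = compute_supremizers(rs.X_u, D_f, Vp, B_list)
        V_u = finalize_basis(Vu, np.column_stack([S_p, S_c]) if S_p.size or S_c.size
                             else np.zeros((rs.free.size, 0)), rs.X_u)
        archive.blocks[kind] = BlockBasis(
            kind, resolution, V_u, Vp, sig_u, sig_p,
            n_pod_u=Vu.shape[1], n_sup_p=S_p.shape[1], n_sup_c=S_c.shape[1],
            mesh_hash=_mesh_hash(rs.block.mesh),
        )
    return archive


def run_offline(geometry_factory, base_params: list, kinds: list,
                pod: PODConfig, basis: InterfaceBasis,
                props: FluidProperties | None = None,
                scheme: BDFScheme | None = None,
                inflow: InflowSpec | None = None,
                t_end: float = 0.1, resolution: int = 6,
                newton: NewtonConfig | None = None) -> BasisArchive:
    """Full offline pipeline: snapshots, then POD and enrichment.

    ``geometry_factory(params_list) -> ModularGeometry`` rebuilds the
    modular geometry for a perturbed parameter set; ``kinds[j]`` is the
    block kind of subdomain j.
    """
    snaps = collect_snapshots(geometry_factory, base_params, kinds, pod, basis,
                              props, scheme, inflow, t_end, newton)
    archive = build_archive(snaps, kinds, pod, basis, resolution)
    archive.metadata.update({"t_end": t_end})
    return archive


def _ref_divergence(rs: ReferenceBlockSpace):
    from .fem import FluidProperties as FP
    from .fem import assemble_constant_operators

    ops = assemble_constant_operators(rs.space, FP(rho_f=1.0, mu_f=1.0))
    return ops.D[:, rs.free]


def _ref_coords_of(blockop: SubdomainOperators) -> np.ndarray:
    """Reference coordinates of the free velocity DOF nodes of a subdomain."""
    ref_mesh = blockop.subdomain.block.mesh
    ref_space_coords = _p2_coords(ref_mesh)
    return ref_space_coords[blockop.free[0::2] // 2]


def _p2_coords(mesh) -> np.ndarray:
    space = build_taylor_hood_space(mesh)
    return space.vel_node_coords()


def _free_to_nodes(blockop: SubdomainOperators, u_free: np.ndarray) -> np.ndarray:
    """(m, 2) nodal values from a free-DOF vector (free DOFs come in x/y
    pairs per node because wall elimination removes both components)."""
    return np.column_stack([u_free[0::2], u_free[1::2]])


def _nodes_to_free(blockop: SubdomainOperators, v_nodes: np.ndarray) -> np.ndarray:
    out = np.empty(v_nodes.shape[0] * 2)
    out[0::2] = v_nodes[:, 0]
    out[1::2] = v_nodes[:, 1]
    return out
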