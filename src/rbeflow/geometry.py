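"""Reference building blocks, parametrized deformations, modular geometries.

A vessel-like domain is approximated as a union of non-overlapping
subdomains, each the image of a reference *building block* under a
parametrized map

    Phi(x) = Q chi(x; mu) + t,

with Q a rotation, t a translation and chi a block-specific nonaffine
deformation.  The block library contains straight tubes with aspect ratios
length/diameter 1:1 (T1), 1:2 (T2) and 1:3 (T3) and a model symmetric
bifurcation (B).  All blocks have unit diameter; interfaces are straight
segments (the 2D analogue of the circular faces), so that any two blocks
can be glued whenever their interface segments coincide.

Tube deformations are analytic (axial stretch, linear radius taper from
inlet to outlet, circular-arc bending of the centreline) and carry an exact
closed-form Jacobian.  The bifurcation is deformed by prescribing rigid
rotations of its outlet segments and extending the boundary displacement
harmonically into the volume; its Jacobian is approximated by the identity,
which is adequate for the small rotations admitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TriMesh, polygon_mesh, rectangle_mesh

__all__ = [
    "InterfaceDescriptor",
    "ReferenceBlock",
    "DeformationParams",
    "GeometricMap",
    "Subdomain",
    "ModularGeometry",
    "build_reference_block",
    "nonaffine_map",
    "apply_deformation",
    "compose_modular_geometry",
    "build_chain",
    "build_tree",
]

WALL_TAG = "wall"

# admissible parameter ranges (ratios, radians); chosen so that the map
# Jacobian stays positive on the whole box (worst case: short tube, widest
# taper, strongest bend)
TUBE_PARAM_SPEC = {
    "length_ratio": (0.75, 2.0),
    "radius_ratio": (0.5, 1.5),
    "bend_angle": (-0.4, 0.4),
}
BIF_PARAM_SPEC = {
    "alpha1": (-0.3, 0.3),
    "alpha2": (-0.3, 0.3),
}

# bifurcation construction constants (unit diameter everywhere)
_BIF_TRUNK = 0.6
_BIF_BRANCH = 1.2
_BIF_HALF_ANGLE = np.pi / 4


@dataclass
class InterfaceDescriptor:
    """A straight interface segment: centre, outward unit normal, half-width."""

    center: np.ndarray
    normal: np.ndarray
    halfwidth: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def matches(self, other: "InterfaceDescriptor", tol: float) -> bool:
        """True if the two descriptors describe the same segment from
        opposite sides, within absolute tolerance ``tol``."""
        return (
            np.linalg.norm(self.center - other.center) < tol
            and abs(self.halfwidth - other.halfwidth) < tol
            and np.linalg.norm(self.normal + other.normal) < tol
        )


@dataclass
class ReferenceBlock:
    kind: str  # 'T1' | 'T2' | 'T3' | 'B'
    mesh: TriMesh
    interfaces: dict  # name -> InterfaceDescriptor (reference frame)
    inlet_names: tuple
    outlet_names: tuple
    wall_tag: str = WALL_TAG
    param_spec: dict = field(default_factory=dict)

    @property
    def is_tube(self) -> bool:
        return self.kind.startswith("T")


@dataclass
class DeformationParams:
    """Deformation parameters mu for one subdomain.

    ``values`` holds the nonaffine parameters (tube: length_ratio,
    radius_ratio, bend_angle; bifurcation: alpha1, alpha2); ``rotation`` is
    the angle of the rigid rotation Q and ``translation`` the vector t.
    """

    values: dict
    rotation: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)

    @property
    def Q(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    @classmethod
    def identity(cls, kind: str) -> "DeformationParams":
        if kind.startswith("T"):
            return cls({"length_ratio": 1.0, "radius_ratio": 1.0, "bend_angle": 0.0})
        return cls({"alpha1": 0.0, "alpha2": 0.0})


def _check_spec(values: dict, spec: dict):
    for k, (lo, hi) in spec.items():
        v = values.get(k)
        if v is None:
            raise ValueError(f"missing deformation parameter '{k}'")
        if not lo <= v <= hi:
            raise ValueError(f"parameter '{k}'={v} outside admissible range [{lo}, {hi}]")


def deformation_parameter_count(kind: str, d: int = 2) -> int:
    """Number of nonaffine deformation parameters of a block kind.

    Tubes have three in either dimension (length ratio, outlet-radius
    ratio, bending angle; the rigid rotation Q absorbs the bending
    direction in 3D).  The bifurcation has one outlet-normal rotation angle
    per outlet in 2D and three Euler angles per outlet in 3D (six in
    total); its radii are not parametrized.
    """
    if kind.startswith("T"):
        return 3
    if kind == "B":
        return {2: 2, 3: 6}[d]
    raise ValueError(f"unknown building-block kind '{kind}'")


def build_reference_block(kind: str, resolution: int) -> ReferenceBlock:
    """Build a reference block mesh.

    ``resolution`` is the number of elements across the (unit) diameter;
    tubes Tk span ``k`` diameters axially.
    """
    if resolution < 2:
        raise ValueError("resolution must give at least 2 elements per direction")
    if kind in ("T1", "T2", "T3"):
        k = int(kind[1])
        mesh = rectangle_mesh(
            k * resolution, resolution, 0.0, float(k), -0.5, 0.5,
            tags=("inlet", "outlet", WALL_TAG, WALL_TAG),
        )
        ifs = {
            "inlet": InterfaceDescriptor([0.0, 0.0], [-1.0, 0.0], 0.5),
            "outlet": InterfaceDescriptor([float(k), 0.0], [1.0, 0.0], 0.5),
        }
        return ReferenceBlock(kind, mesh, ifs, ("inlet",), ("outlet",),
                              param_spec=dict(TUBE_PARAM_SPEC))
    if kind == "B":
        verts, tags, ifs = _bifurcation_polygon()
        mesh = polygon_mesh(verts, tags, h=1.0 / resolution)
        return ReferenceBlock(kind, mesh, ifs, ("inlet",), ("outlet1", "outlet2"),
                              param_spec=dict(BIF_PARAM_SPEC))
    raise ValueError(f"unknown building-block kind '{kind}'")


def _bifurcation_polygon():
    """Vertices, per-side tags and interface descriptors of the symmetric Y."""
    th = _BIF_HALF_ANGLE
    c, s = np.cos(th), np.sin(th)
    d_up, d_dn = np.array([c, s]), np.array([c, -s])
    n_up = np.array([-s, c])  # left normal of upper branch direction
    J = np.array([_BIF_TRUNK, 0.0])
    O_up = J + _BIF_BRANCH * d_up
    O_dn = J + _BIF_BRANCH * d_dn
    # outer-wall turn point: straight wall y=+0.5 meets the offset line J + 0.5 n_up + t d_up
    t_outer = (0.5 - 0.5 * c) / s
    H = J + 0.5 * n_up + t_outer * d_up  # = (xb, 0.5)
    # inner wedge apex: lower wall of upper branch meets the x-axis
    t_inner = 0.5 * c / s
    W = J - 0.5 * n_up + t_inner * d_up  # on y = 0
    verts = np.array([
        [0.0, -0.5],                       # inlet lower corner
        [H[0], -0.5],                      # lower outer turn
        O_dn - 0.5 * np.array([s, c]),     # lower branch outer corner = O_dn + 0.5*(-n_dn)... mirrored
        O_dn + 0.5 * np.array([-s, c]) * -1 + np.array([0, 0]),  # placeholder, fixed below
        [W[0], 0.0],
        O_up - 0.5 * n_up,
        O_up + 0.5 * n_up,
        [H[0], 0.5],
        [0.0, 0.5],
    ])
    # corners of the outlet segments, mirrored for the lower branch
    n_dn = np.array([s, c])  # left normal of lower branch direction
    verts[2] = O_dn - 0.5 * n_dn
    verts[3] = O_dn + 0.5 * n_dn
    tags = [WALL_TAG, WALL_TAG, "outlet2", WALL_TAG, WALL_TAG, "outlet1",
            WALL_TAG, WALL_TAG, "inlet"]
    ifs = {
        "inlet": InterfaceDescriptor([0.0, 0.0], [-1.0, 0.0], 0.5),
        "outlet1": InterfaceDescriptor(O_up, d_up, 0.5),
        "outlet2": InterfaceDescriptor(O_dn, d_dn, 0.5),
    }
    return verts, tags, ifs


@dataclass
class GeometricMap:
    """Composite map Phi = Q chi + t with pointwise Jacobian J = Q Jchi."""

    block: ReferenceBlock
    params: DeformationParams
    _chi: object = field(repr=False, default=None)  # callable pts -> pts
    _jchi: object = field(repr=False, default=None)  # callable pts -> (m,2,2)

    def chi(self, pts: np.ndarray) -> np.ndarray:
        return self._chi(np.atleast_2d(np.asarray(pts, dtype=float)))

    def phi(self, pts: np.ndarray) -> np.ndarray:
        return self.chi(pts) @ self.params.Q.T + self.params.translation

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        """J_Phi = Q Jchi at the given reference points, (m, 2, 2)."""
        jc = self._jchi(np.atleast_2d(np.asarray(pts, dtype=float)))
        return np.einsum("ij,mjk->mik", self.params.Q, jc)


def nonaffine_map(block: ReferenceBlock, params: DeformationParams) -> GeometricMap:
    """Build the deformation map for a block and admissible parameters."""
    _check_spec(params.values, block.param_spec)
    if block.is_tube:
        chi, jchi = _tube_map(block, params.values)
    else:
        chi, jchi = _bifurcation_map(block, params.values)
    return GeometricMap(block, params, chi, jchi)


def _tube_map(block: ReferenceBlock, vals: dict):
    L_ref = float(block.kind[1])
    s_len = vals["length_ratio"]
    s_rad = vals["radius_ratio"]
    alpha = vals["bend_angle"]
    # inlet half-width may be inherited from an upstream interface so that
    # composed geometries remain conforming at the segment level
    scale = vals.get("inlet_radius", 0.5) / 0.5
    L = s_len * L_ref

    def frames(xi):
        a = alpha * xi
        tang = np.column_stack([np.cos(a), np.sin(a)])
        nrm = np.column_stack([-np.sin(a), np.cos(a)])
        return tang, nrm

    def centreline(xi):
        if abs(alpha) < 1e-14:
            return np.column_stack([L * xi, np.zeros_like(xi)])
        kappa = alpha / L
        return np.column_stack([np.sin(alpha * xi) / kappa, (1 - np.cos(alpha * xi)) / kappa])

    def chi(pts):
        xi = pts[:, 0] / L_ref
        yy = pts[:, 1]
        r = scale * (1 + (s_rad - 1) * xi)
        _, nrm = frames(xi)
        return centreline(xi) + (r * yy)[:, None] * nrm

    def jchi(pts):
        xi = pts[:, 0] / L_ref
        yy = pts[:, 1]
        r = scale * (1 + (s_rad - 1) * xi)
        rp = scale * (s_rad - 1)
        tang, nrm = frames(xi)
        out = np.empty((pts.shape[0], 2, 2))
        col_x = (s_len - alpha * r * yy / L_ref)[:, None] * tang + (rp * yy / L_ref)[:, None] * nrm
        col_y = r[:, None] * nrm
        out[:, :, 0] = col_x
        out[:, :, 1] = col_y
        return out

    return chi, jchi


def _p1_laplacian(mesh: TriMesh) -> sp.csr_matrix:
    p = mesh.points[mesh.cells]
    jac = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)
    detj = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    invj = np.empty_like(jac)
    invj[:, 0, 0] = jac[:, 1, 1] / detj
    invj[:, 0, 1] = -jac[:, 0, 1] / detj
    invj[:, 1, 0] = -jac[:, 1, 0] / detj
    invj[:, 1, 1] = jac[:, 0, 0] / detj
    dref = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    g = np.einsum("ak,ekj->eaj", dref, invj)  # (e, 3, 2)
    loc = 0.5 * np.abs(detj)[:, None, None] * np.einsum("eaj,ebj->eab", g, g)
    rows = np.repeat(mesh.cells, 3, axis=1)
    cols = np.tile(mesh.cells, (1, 3))
    return sp.coo_matrix(
        (loc.ravel(), (rows.ravel(), cols.ravel())),
        shape=(mesh.n_points, mesh.n_points),
    ).tocsr()


def _bifurcation_map(block: ReferenceBlock, vals: dict):
    """Harmonic extension of rigid outlet rotations; Jchi approximated by I."""
    mesh = block.mesh
    A = _p1_laplacian(mesh)
    disp = np.zeros((mesh.n_points, 2))
    fixed = np.zeros(mesh.n_points, dtype=bool)

    inlet_nodes = np.unique(mesh.edges_with_tag("inlet").ravel())
    fixed[inlet_nodes] = True
    for name, key in (("outlet1", "alpha1"), ("outlet2", "alpha2")):
        ang = vals[key]
        desc = block.interfaces[name]
        nodes = np.unique(mesh.edges_with_tag(name).ravel())
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s], [s, c]])
        rel = mesh.points[nodes] - desc.center
        disp[nodes] = rel @ (R.T - np.eye(2))
        fixed[nodes] = True

    free = ~fixed
    Aff = A[np.ix_(np.where(free)[0], np.where(free)[0])]
    Afc = A[np.ix_(np.where(free)[0], np.where(fixed)[0])]
    lu = spla.splu(Aff.tocsc())
    for c in range(2):
        disp[free, c] = lu.solve(-Afc @ disp[fixed, c])

    from scipy.interpolate import LinearNDInterpolator

    interp = LinearNDInterpolator(mesh.points, disp, fill_value=0.0)

    def chi(pts):
        return pts + interp(pts)

    def jchi(pts):
        return np.broadcast_to(np.eye(2), (pts.shape[0], 2, 2)).copy()

    return chi, jchi


@dataclass
class Subdomain:
    block: ReferenceBlock
    map: GeometricMap
    mesh: TriMesh  # deformed
    interfaces: dict  # name -> deformed InterfaceDescriptor

    @property
    def kind(self) -> str:
        return self.block.kind


def apply_deformation(block: ReferenceBlock, gmap: GeometricMap) -> Subdomain:
    """Map the reference mesh through Phi and recompute interface descriptors."""
    if gmap.block is not block:
        raise ValueError("map was built for a different block")
    new_pts = gmap.phi(block.mesh.points)
    mesh = block.mesh.copy_with_points(new_pts)
    if np.any(mesh.signed_cell_areas() <= 0):
        raise ValueError("deformation produced inverted elements")

    ifs = {}
    for name, ref_desc in block.interfaces.items():
        nodes = np.unique(block.mesh.edges_with_tag(name).ravel())
        pts = mesh.points[nodes]
        # endpoints = the two extreme points along the segment
        dvec = pts - pts.mean(axis=0)
        t_ref = np.array([-ref_desc.normal[1], ref_desc.normal[0]])
        proj = (block.mesh.points[nodes] - ref_desc.center) @ t_ref
        p0, p1 = pts[np.argmin(proj)], pts[np.argmax(proj)]
        center = 0.5 * (p0 + p1)
        halfwidth = 0.5 * np.linalg.norm(p1 - p0)
        tang = (p1 - p0) / np.linalg.norm(p1 - p0)
        nrm = np.array([tang[1], -tang[0]])
        # orient outward: away from the image of a point just inside
        probe = gmap.phi(ref_desc.center[None, :] - 1e-3 * ref_desc.normal[None, :])[0]
        if np.dot(nrm, center - probe) < 0:
            nrm = -nrm
        # straightness check (segment fit residual)
        resid = np.abs((pts - center) @ nrm)
        if resid.max() > 1e-8 * max(halfwidth, 1.0):
            raise ValueError(f"deformed interface '{name}' is not straight")
        ifs[name] = InterfaceDescriptor(center, nrm, halfwidth)
    return Subdomain(block, gmap, mesh, ifs)


@dataclass
class ModularGeometry:
    subdomains: list
    internal: list  # (j, name_j, m, name_m, InterfaceDescriptor of the + side)
    inlets: list  # (j, name, InterfaceDescriptor)
    outlets: list  # (j, name, InterfaceDescriptor)

    @property
    def n_subdomains(self) -> int:
        return len(self.subdomains)

    def neighbours(self, j: int) -> set:
        out = set()
        for a, _, b, _, _ in self.internal:
            if a == j:
                out.add(b)
            elif b == j:
                out.add(a)
        return out


def compose_modular_geometry(subdomains, topology, inlets, tol_rel: float = 1e-6) -> ModularGeometry:
    """Glue subdomains along matching interface descriptors.

    ``topology`` is a list of ((j, name_j), (m, name_m)) pairs; ``inlets`` a
    list of (j, name).  The subdomain with the lower index is the "+" side
    of each internal interface and owns the canonical descriptor (sign
    convention c = +1).  Interfaces neither paired nor inlets become
    outlets (natural boundary).
    """
    internal = []
    used = set()
    for (j, nj), (m, nm) in topology:
        if j == m:
            raise ValueError("an interface must join two distinct subdomains")
        try:
            dj = subdomains[j].interfaces[nj]
            dm = subdomains[m].interfaces[nm]
        except (KeyError, IndexError) as exc:
            raise ValueError(f"dangling interface reference: {exc}") from exc
        tol = tol_rel * max(dj.halfwidth, 1.0)
        if not dj.matches(dm, max(tol, 1e-12)):
            raise ValueError(
                f"interface mismatch between subdomain {j}:{nj} and {m}:{nm} "
                f"(centres {dj.center} vs {dm.center})"
            )
        if j < m:
            internal.append((j, nj, m, nm, dj))
        else:
            internal.append((m, nm, j, nj, dm))
        used.add((j, nj))
        used.add((m, nm))

    inlet_list = []
    for j, name in inlets:
        if (j, name) in used:
            raise ValueError(f"inlet ({j}, {name}) already used as internal interface")
        inlet_list.append((j, name, subdomains[j].interfaces[name]))
        used.add((j, name))

    outlet_list = []
    for j, sd in enumerate(subdomains):
        for name, desc in sd.interfaces.items():
            if (j, name) not in used:
                outlet_list.append((j, name, desc))
    return ModularGeometry(list(subdomains), internal, inlet_list, outlet_list)


def _placed_subdomain(kind: str, params: DeformationParams, resolution: int,
                      attach_to: InterfaceDescriptor | None,
                      blocks_cache: dict) -> Subdomain:
    """Deform a block and rigidly place it so its inlet matches ``attach_to``.

    Tubes inherit the attachment half-width (segment-conforming gluing); a
    bifurcation requires the attachment to carry the reference half-width,
    since its radii are not parametrized.
    """
    if kind not in blocks_cache:
        blocks_cache[kind] = build_reference_block(kind, resolution)
    block = blocks_cache[kind]
    if attach_to is not None:
        vals = dict(params.values)
        if block.is_tube:
            vals["inlet_radius"] = attach_to.halfwidth
        elif abs(attach_to.halfwidth - 0.5) > 1e-9:
            raise ValueError(
                "bifurcation inlet requires half-width 0.5; taper the "
                "upstream tube back to the reference radius"
            )
        n = attach_to.normal
        params = DeformationParams(
            vals,
            rotation=float(np.arctan2(n[1], n[0])),
            translation=attach_to.center,
        )
    gmap = nonaffine_map(block, params)
    return apply_deformation(block, gmap)


def build_chain(kinds, params_list=None, resolution: int = 6):
    """A chain of tubes glued end-to-end, inlet on the first block.

    Returns a ModularGeometry with len(kinds) - 1 internal interfaces.
    """
    if params_list is None:
        params_list = [DeformationParams.identity(k) for k in kinds]
    cache = {}
    subs = []
    attach = None
    for kind, par in zip(kinds, params_list):
        sd = _placed_subdomain(kind, par, resolution, attach, cache)
        subs.append(sd)
        attach = sd.interfaces["outlet"]
    topo = [(((i, "outlet")), ((i + 1, "inlet"))) for i in range(len(subs) - 1)]
    return compose_modular_geometry(subs, topo, inlets=[(0, "inlet")])


def build_tree(trunk_kinds, branch_kinds, params=None, resolution: int = 6):
    """Tree: a chain of tubes, a bifurcation, then a chain of tubes on each
    branch.  ``branch_kinds`` is a pair of kind lists.  With 4 trunk tubes
    and 2 tubes per branch this reproduces the 9-subdomain layout
    (8 internal interfaces, 1 inlet, 2 outlets)."""
    cache = {}
    subs, topo = [], []
    if params is None:
        params = {}

    def par_for(idx, kind):
        return params.get(idx, DeformationParams.identity(kind))

    attach = None
    for pos, kind in enumerate(trunk_kinds):
        par = par_for(len(subs), kind)
        if pos == len(trunk_kinds) - 1:
            # the tube feeding the bifurcation tapers back to the reference
            # half-width (bifurcation radii are not parametrized)
            vals = dict(par.values)
            r_in = attach.halfwidth if attach is not None else 0.5
            vals["radius_ratio"] = 0.5 / r_in
            par = DeformationParams(vals, par.rotation, par.translation.copy())
        sd = _placed_subdomain(kind, par, resolution, attach, cache)
        if subs:
            topo.append(((len(subs) - 1, "outlet"), (len(subs), "inlet")))
        subs.append(sd)
        attach = sd.interfaces["outlet"]

    bif = _placed_subdomain("B", par_for(len(subs), "B"), resolution, attach, cache)
    bif_idx = len(subs)
    if subs:
        topo.append(((bif_idx - 1, "outlet"), (bif_idx, "inlet")))
    subs.append(bif)

    for b, kinds in enumerate(branch_kinds):
        attach = bif.interfaces[f"outlet{b + 1}"]
        prev = (bif_idx, f"outlet{b + 1}")
        for kind in kinds:
            sd = _placed_subdomain(kind, par_for(len(subs), kind), resolution, attach, cache)
            topo.append((prev, (len(subs), "inlet")))
            prev = (len(subs), "outlet")
            subs.append(sd)
            attach = sd.interfaces["outlet"]
    return compose_modular_geometry(subs, topo, inlets=[(0, "inlet")])
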