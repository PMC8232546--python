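"""Simplicial meshes: container, structured generators, text I/O.

Meshes are plain triangle meshes with string-tagged boundary edges.  Every
boundary edge carries exactly one tag (a wall marker or an interface name);
this is what the finite-element layer uses to locate walls, inlets, outlets
and coupling interfaces.

Generators are deliberately simple: mapped structured triangulations for
rectangles (tubes) and a clipped-Delaunay mesh for polygonal blocks
(bifurcations).  I/O covers Gmsh v2.2 ASCII and XML-ASCII VTU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["TriMesh", "rectangle_mesh", "polygon_mesh", "write_gmsh", "read_gmsh", "write_vtu"]


@dataclass
class TriMesh:
    points: np.ndarray  # (n_pts, 2)
    cells: np.ndarray  # (n_tri, 3) int
    boundary_edges: np.ndarray  # (n_bed, 2) int, vertex pairs
    boundary_tags: np.ndarray  # (n_bed,) str
    field_data: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.boundary_edges = np.asarray(self.boundary_edges, dtype=np.int64).reshape(-1, 2)
        self.boundary_tags = np.asarray(self.boundary_tags, dtype=object)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def cell_areas(self) -> np.ndarray:
        p = self.points[self.cells]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def signed_cell_areas(self) -> np.ndarray:
        p = self.points[self.cells]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def orient(self) -> "TriMesh":
        """Flip cells to counterclockwise orientation in place."""
        neg = self.signed_cell_areas() < 0
        self.cells[neg] = self.cells[neg][:, [0, 2, 1]]
        return self

    def edges_with_tag(self, tag: str) -> np.ndarray:
        return self.boundary_edges[self.boundary_tags == tag]

    def tags(self):
        return sorted(set(self.boundary_tags.tolist()))

    def copy_with_points(self, new_points: np.ndarray) -> "TriMesh":
        """Same connectivity (element arrays shared by value), new coordinates."""
        return TriMesh(
            points=np.asarray(new_points, dtype=float),
            cells=self.cells.copy(),
            boundary_edges=self.boundary_edges.copy(),
            boundary_tags=self.boundary_tags.copy(),
            field_data=dict(self.field_data),
        )


def rectangle_mesh(
    nx: int,
    ny: int,
    x0: float = 0.0,
    x1: float = 1.0,
    y0: float = 0.0,
    y1: float = 1.0,
    tags=("left", "right", "bottom", "top"),
) -> TriMesh:
    """Structured crossed-diagonal triangulation of a rectangle.

    ``nx``/``ny`` are element counts per direction; each quad is split along
    alternating diagonals (union-jack) so the mesh has no preferred bias.
    """
    if nx < 1 or ny < 1:
        raise ValueError("need at least one element per direction")
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])

    def vid(i, j):
        return i * (ny + 1) + j

    cells = []
    for i in range(nx):
        for j in range(ny):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            if (i + j) % 2 == 0:
                cells += [[a, b, c], [a, c, d]]
            else:
                cells += [[a, b, d], [b, c, d]]
    bed, btag = [], []
    tleft, tright, tbot, ttop = tags
    for j in range(ny):
        bed.append([vid(0, j), vid(0, j + 1)]); btag.append(tleft)
        bed.append([vid(nx, j), vid(nx, j + 1)]); btag.append(tright)
    for i in range(nx):
        bed.append([vid(i, 0), vid(i + 1, 0)]); btag.append(tbot)
        bed.append([vid(i, ny + 0), vid(i + 1, ny)]); btag.append(ttop)
    return TriMesh(pts, np.array(cells), np.array(bed), np.array(btag, dtype=object)).orient()


def polygon_mesh(vertices: np.ndarray, edge_tags, h: float) -> TriMesh:
    """Delaunay mesh of a simple polygon with target spacing ``h``.

    ``edge_tags[i]`` tags polygon side (v_i, v_{i+1}).  Interior points come
    from a regular grid clipped to the polygon (points closer than 0.4 h to
    the boundary are dropped to avoid slivers); boundary points are placed
    equispaced on each side.  Triangles whose centroid falls outside the
    polygon are removed, which handles the nonconvex notch of bifurcations.
    """
    from shapely.geometry import Point, Polygon

    verts = np.asarray(vertices, dtype=float)
    nv = verts.shape[0]
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValueError("invalid polygon")

    bpts = []
    side_of = []  # polygon side index per boundary point run
    for i in range(nv):
        a, b = verts[i], verts[(i + 1) % nv]
        npts = max(1, int(round(np.linalg.norm(b - a) / h)))
        for k in range(npts):  # exclude endpoint; next side provides it
            bpts.append(a + (b - a) * (k / npts))
            side_of.append(i)
    bpts = np.array(bpts)

    xmin, ymin = verts.min(axis=0)
    xmax, ymax = verts.max(axis=0)
    gx = np.arange(xmin + 0.5 * h, xmax, h)
    gy = np.arange(ymin + 0.5 * h, ymax, h)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    grid = np.column_stack([GX.ravel(), GY.ravel()])
    bnd = poly.exterior
    keep = np.array(
        [poly.contains(Point(p)) and bnd.distance(Point(p)) > 0.4 * h for p in grid]
    )
    interior = grid[keep]

    allpts = np.vstack([bpts, interior])
    tri = Delaunay(allpts)
    cells = tri.simplices
    centroids = allpts[cells].mean(axis=1)
    inside = np.array([poly.contains(Point(c)) for c in centroids])
    cells = cells[inside]

    # drop unreferenced points and reindex
    used = np.unique(cells)
    remap = -np.ones(allpts.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    pts = allpts[used]
    cells = remap[cells]

    # boundary edges: edges belonging to exactly one triangle
    e = np.sort(
        np.vstack([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    bedges = uniq[counts == 1]

    # tag each boundary edge by the nearest polygon side of its midpoint
    mids = 0.5 * (pts[bedges[:, 0]] + pts[bedges[:, 1]])
    tags = []
    from shapely.geometry import LineString

    sides = [LineString([verts[i], verts[(i + 1) % nv]]) for i in range(nv)]
    for m in mids:
        pm = Point(m)
        d = [s.distance(pm) for s in sides]
        tags.append(edge_tags[int(np.argmin(d))])
    mesh = TriMesh(pts, cells, bedges, np.array(tags, dtype=object)).orient()
    if mesh.cell_areas().min() <= 1e-14:
        raise ValueError("degenerate element in polygon mesh; adjust h")
    return mesh


# ----------------------------------------------------------------- text I/O

def write_gmsh(mesh: TriMesh, path: str) -> None:
    """Write Gmsh v2.2 ASCII with physical names for boundary tags."""
    tags = mesh.tags()
    tag_id = {t: i + 1 for i, t in enumerate(tags)}
    surf_id = len(tags) + 1
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n%d\n" % (len(tags) + 1))
        for t in tags:
            f.write('1 %d "%s"\n' % (tag_id[t], t))
        f.write('2 %d "domain"\n' % surf_id)
        f.write("$EndPhysicalNames\n$Nodes\n%d\n" % mesh.n_points)
        for i, p in enumerate(mesh.points):
            f.write("%d %.16g %.16g 0\n" % (i + 1, p[0], p[1]))
        f.write("$EndNodes\n$Elements\n%d\n" % (len(mesh.boundary_edges) + mesh.n_cells))
        eid = 1
        for (a, b), t in zip(mesh.boundary_edges, mesh.boundary_tags):
            f.write("%d 1 2 %d %d %d %d\n" % (eid, tag_id[t], tag_id[t], a + 1, b + 1))
            eid += 1
        for c in mesh.cells:
            f.write("%d 2 2 %d %d %d %d %d\n" % (eid, surf_id, surf_id, c[0] + 1, c[1] + 1, c[2] + 1))
            eid += 1
        f.write("$EndElements\n")


def read_gmsh(path: str) -> TriMesh:
    """Read a Gmsh v2.2 ASCII file written by :func:`write_gmsh` (or any
    2.2 file with line elements tagged by physical groups)."""
    with open(path) as f:
        lines = f.read().splitlines()
    names = {}
    i = 0
    pts, cells, bed, btag = [], [], [], []
    while i < len(lines):
        ln = lines[i]
        if ln == "$PhysicalNames":
            n = int(lines[i + 1])
            for k in range(n):
                dim, pid, nm = lines[i + 2 + k].split(maxsplit=2)
                names[(int(dim), int(pid))] = nm.strip('"')
            i += n + 2
        elif ln == "$Nodes":
            n = int(lines[i + 1])
            for k in range(n):
                parts = lines[i + 2 + k].split()
                pts.append([float(parts[1]), float(parts[2])])
            i += n + 2
        elif ln == "$Elements":
            n = int(lines[i + 1])
            for k in range(n):
                parts = [int(v) for v in lines[i + 2 + k].split()]
                etype, ntags = parts[1], parts[2]
                tags_ = parts[3:3 + ntags]
                conn = parts[3 + ntags:]
                if etype == 1:
                    bed.append([conn[0] - 1, conn[1] - 1])
                    btag.append(names.get((1, tags_[0]), str(tags_[0])))
                elif etype == 2:
                    cells.append([c - 1 for c in conn])
            i += n + 2
        else:
            i += 1
    return TriMesh(
        np.array(pts), np.array(cells), np.array(bed), np.array(btag, dtype=object)
    ).orient()


def write_vtu(path: str, mesh: TriMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write an XML-ASCII VTU file (triangles; vectors padded to 3D)."""

    def arr_block(name, data):
        data = np.asarray(data, dtype=float)
        if data.ndim == 2 and data.shape[1] == 2:
            data = np.column_stack([data, np.zeros(len(data))])
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        body = "\n".join(" ".join("%.9g" % v for v in np.atleast_1d(row)) for row in data)
        return (
            f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{ncomp}" format="ascii">\n'
            + body + "\n</DataArray>\n"
        )

    npts, ncl = mesh.n_points, mesh.n_cells
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n<VTKFile type="UnstructuredGrid" version="0.1">\n')
        f.write(f'<UnstructuredGrid><Piece NumberOfPoints="{npts}" NumberOfCells="{ncl}">\n')
        f.write("<Points>\n")
        f.write(arr_block("points", np.column_stack([mesh.points, np.zeros(npts)])))
        f.write("</Points>\n<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        f.write("\n".join(" ".join(str(v) for v in c) for c in mesh.cells))
        f.write('\n</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        f.write(" ".join(str(3 * (i + 1)) for i in range(ncl)))
        f.write('\n</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        f.write(" ".join("5" for _ in range(ncl)))
        f.write("\n</DataArray>\n</Cells>\n")
        if point_data:
            f.write("<PointData>\n")
            for nm, d in point_data.items():
                f.write(arr_block(nm, d))
            f.write("</PointData>\n")
        if cell_data:
            f.write("<CellData>\n")
            for nm, d in cell_data.items():
                f.write(arr_block(nm, d))
            f.write("</CellData>\n")
        f.write("</Piece></UnstructuredGrid></VTKFile>\n")
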