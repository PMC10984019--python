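"""Lofting of axial outlines into 3D lung-section solids and tetrahedral
meshing with quadratic (10-node) elements.

The lofted model carries two nested solids: the outer solid (the traced lung
wall, where boundary conditions live) and the inner solid (the cropped extent
of the stiffness maps, where material properties are specified directly).
The mesh is generated by sweeping a triangulated cross-section template along
z and splitting the resulting prisms into tetrahedra with the minimum-vertex
diagonal rule, which guarantees a conforming partition; midside nodes are
edge midpoints, so every element is a straight-sided (affine) quadratic tet.

Node ordering follows the VTK quadratic-tetrahedron convention: corners
0-3, then midsides on edges (0,1), (1,2), (2,0), (0,3), (1,3), (2,3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, RegularGridInterpolator
from scipy import ndimage

from .synthetic import AxialOutlineStack

TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))
# local faces of a tet (corners), outward when the tet is positively oriented
TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))


class MeshingError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# mesh container
# --------------------------------------------------------------------------

@dataclass
class TetMesh:
    nodes: np.ndarray           # (n_nodes, 3) m; vertices first, then midsides
    elements: np.ndarray        # (n_el, 10) int
    n_vertices: int
    domain: np.ndarray          # (n_el,) 0 = inner solid, 1 = outer shell
    face_labels: dict[str, np.ndarray] = field(default_factory=dict)
    # each label -> (n_faces, 7): 6 tri6 node ids + owning element id

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def corner_coords(self) -> np.ndarray:
        return self.nodes[self.elements[:, :4]]

    def element_volumes(self) -> np.ndarray:
        x = self.corner_coords()
        d = x[:, 1:] - x[:, :1]
        return np.einsum("ei,ei->e", d[:, 0],
                         np.cross(d[:, 1], d[:, 2])) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.corner_coords().mean(axis=1)

    def volume(self, domain: int | None = None) -> float:
        v = self.element_volumes()
        if domain is not None:
            v = v[self.domain == domain]
        return float(v.sum())

    def max_edge_length(self) -> float:
        x = self.nodes[self.elements[:, :4]]
        lengths = []
        for a, b in TET10_EDGES:
            lengths.append(np.linalg.norm(x[:, a] - x[:, b], axis=1))
        return float(np.max(lengths))


# --------------------------------------------------------------------------
# quadratic nodes, boundary faces
# --------------------------------------------------------------------------

def _tet4_to_tet10(vertices: np.ndarray, tets: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Insert unique midside nodes; returns (nodes, tet10 connectivity)."""
    edges = {}
    n_v = vertices.shape[0]
    conn = np.empty((tets.shape[0], 10), dtype=np.int64)
    conn[:, :4] = tets
    mid_coords = []
    for e in range(tets.shape[0]):
        for j, (a, b) in enumerate(TET10_EDGES):
            va, vb = tets[e, a], tets[e, b]
            key = (va, vb) if va < vb else (vb, va)
            idx = edges.get(key)
            if idx is None:
                idx = n_v + len(mid_coords)
                edges[key] = idx
                mid_coords.append(0.5 * (vertices[va] + vertices[vb]))
            conn[e, 4 + j] = idx
    nodes = np.vstack([vertices, np.asarray(mid_coords)])
    return nodes, conn


def _orient_positive(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    d = vertices[tets[:, 1:]] - vertices[tets[:, :1]]
    vol = np.einsum("ei,ei->e", d[:, 0], np.cross(d[:, 1], d[:, 2]))
    flip = vol < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets


_EDGE_OF_PAIR = {}
for _j, (_a, _b) in enumerate(TET10_EDGES):
    _EDGE_OF_PAIR[(_a, _b)] = 4 + _j
    _EDGE_OF_PAIR[(_b, _a)] = 4 + _j


def boundary_faces(elements: np.ndarray) -> np.ndarray:
    """Boundary tri6 faces as (n_faces, 7): 6 node ids + owning element.

    Corner triples are oriented outward (positively oriented elements
    assumed); midside columns follow (a,b), (b,c), (c,a).
    """
    faces = {}
    for e in range(elements.shape[0]):
        for local in TET_FACES:
            tri = tuple(elements[e, i] for i in local)
            key = tuple(sorted(tri))
            if key in faces:
                faces[key] = None
            else:
                mids = (elements[e, _EDGE_OF_PAIR[(local[0], local[1])]],
                        elements[e, _EDGE_OF_PAIR[(local[1], local[2])]],
                        elements[e, _EDGE_OF_PAIR[(local[2], local[0])]])
                faces[key] = tri + mids + (e,)
    return np.asarray([f for f in faces.values() if f is not None],
                      dtype=np.int64)


def face_normals_areas(nodes: np.ndarray, faces: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    a = nodes[faces[:, 0]]
    b = nodes[faces[:, 1]]
    c = nodes[faces[:, 2]]
    cr = np.cross(b - a, c - a)
    area2 = np.linalg.norm(cr, axis=1)
    return cr / area2[:, None], area2 / 2.0


# --------------------------------------------------------------------------
# prism and hex splitting
# --------------------------------------------------------------------------

_PRISM_PERMS = {
    0: (0, 1, 2, 3, 4, 5),
    1: (1, 2, 0, 4, 5, 3),
    2: (2, 0, 1, 5, 3, 4),
    3: (3, 5, 4, 0, 2, 1),
    4: (4, 3, 5, 1, 0, 2),
    5: (5, 4, 3, 2, 1, 0),
}


def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (bottom 0,1,2 / top 3,4,5) into 3 tets each.

    Every quad face receives the diagonal through its smallest global vertex,
    so adjacent prisms agree on shared faces and the mesh is conforming.
    """
    tets = np.empty((prisms.shape[0] * 3, 4), dtype=np.int64)
    for i, p in enumerate(prisms):
        v = p[list(_PRISM_PERMS[int(np.argmin(p))])]
        if min(v[1], v[5]) < min(v[2], v[4]):
            t = [(v[0], v[1], v[2], v[5]),
                 (v[0], v[1], v[5], v[4]),
                 (v[0], v[4], v[5], v[3])]
        else:
            t = [(v[0], v[1], v[2], v[4]),
                 (v[0], v[4], v[2], v[5]),
                 (v[0], v[4], v[5], v[3])]
        tets[3 * i:3 * i + 3] = t
    return tets


_CUBE_TET_PATHS = [
    (0b000, 0b100, 0b110, 0b111),
    (0b000, 0b100, 0b101, 0b111),
    (0b000, 0b010, 0b110, 0b111),
    (0b000, 0b010, 0b011, 0b111),
    (0b000, 0b001, 0b101, 0b111),
    (0b000, 0b001, 0b011, 0b111),
]


def box_tet_mesh(shape: tuple[int, int, int],
                 bounds: tuple[tuple[float, float], ...] = ((0, 1),) * 3,
                 ) -> TetMesh:
    """Structured box mesh: each cell split into 6 tets around its main
    diagonal (conforming across cells).  Face labels: x-, x+, y-, y+, z-, z+.
    """
    nx, ny, nz = shape
    xs = [np.linspace(lo, hi, n + 1) for (lo, hi), n in zip(bounds, shape)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
    verts = grid.reshape(-1, 3)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = {}
                for bits in range(8):
                    corner[bits] = vid(i + (bits >> 2 & 1), j + (bits >> 1 & 1),
                                       k + (bits & 1))
                for path in _CUBE_TET_PATHS:
                    tets.append([corner[b] for b in path])
    tets = _orient_positive(verts, np.asarray(tets, dtype=np.int64))
    nodes, conn = _tet4_to_tet10(verts, tets)
    mesh = TetMesh(nodes=nodes, elements=conn, n_vertices=verts.shape[0],
                   domain=np.zeros(conn.shape[0], dtype=np.int8))
    faces = boundary_faces(conn)
    normals, _ = face_normals_areas(nodes, faces)
    labels = {}
    for name, vec in (("x-", (-1, 0, 0)), ("x+", (1, 0, 0)),
                      ("y-", (0, -1, 0)), ("y+", (0, 1, 0)),
                      ("z-", (0, 0, -1)), ("z+", (0, 0, 1))):
        sel = normals @ np.asarray(vec, dtype=float) > 0.99
        labels[name] = faces[sel]
    mesh.face_labels = labels
    return mesh


def ball_tet_mesh(radius: float, n: int = 6,
                  center: tuple[float, float, float] = (0.0, 0.0, 0.0)
                  ) -> TetMesh:
    """Ball mesh from a structured cube mapped smoothly onto the ball.

    All boundary faces carry the single label ``surface``.
    """
    nx = n
    xs = np.linspace(-1, 1, nx + 1)
    grid = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1)
    p = grid.reshape(-1, 3)
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    mapped = np.column_stack([
        x * np.sqrt(np.maximum(1 - y**2 / 2 - z**2 / 2 + y**2 * z**2 / 3, 0)),
        y * np.sqrt(np.maximum(1 - z**2 / 2 - x**2 / 2 + z**2 * x**2 / 3, 0)),
        z * np.sqrt(np.maximum(1 - x**2 / 2 - y**2 / 2 + x**2 * y**2 / 3, 0)),
    ]) * radius + np.asarray(center)

    def vid(i, j, k):
        return (i * (nx + 1) + j) * (nx + 1) + k

    tets = []
    for i in range(nx):
        for j in range(nx):
            for k in range(nx):
                corner = {bits: vid(i + (bits >> 2 & 1), j + (bits >> 1 & 1),
                                    k + (bits & 1)) for bits in range(8)}
                for path in _CUBE_TET_PATHS:
                    tets.append([corner[b] for b in path])
    tets = _orient_positive(mapped, np.asarray(tets, dtype=np.int64))
    nodes, conn = _tet4_to_tet10(mapped, tets)
    mesh = TetMesh(nodes=nodes, elements=conn, n_vertices=mapped.shape[0],
                   domain=np.zeros(conn.shape[0], dtype=np.int8))
    mesh.face_labels = {"surface": boundary_faces(conn)}
    return mesh


# --------------------------------------------------------------------------
# lofting
# --------------------------------------------------------------------------

@dataclass
class LoftedSurface:
    """Smooth loft through per-slice outline rings.

    Rings are arc-length resampled to a common vertex count with the seam
    aligned to a shared reference angle; a natural cubic spline interpolates
    each ring vertex across z.
    """

    rings: np.ndarray   # (n_slices, n_theta, 2)
    z: np.ndarray       # (n_slices,)
    _spline: CubicSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._spline = CubicSpline(self.z, self.rings, axis=0, bc_type="natural")

    def cross_section(self, z: float, n_theta: int | None = None) -> np.ndarray:
        z = float(np.clip(z, self.z[0], self.z[-1]))
        ring = self._spline(z)
        if n_theta is None or n_theta == ring.shape[0]:
            return ring
        # periodic linear resample over vertex index
        m = ring.shape[0]
        t = np.arange(m + 1)
        closed = np.vstack([ring, ring[:1]])
        ti = np.linspace(0, m, n_theta, endpoint=False)
        out = np.empty((n_theta, 2))
        for c in range(2):
            out[:, c] = np.interp(ti, t, closed[:, c])
        return out

    def volume(self, n_sub: int = 400) -> float:
        zz = np.linspace(self.z[0], self.z[-1], n_sub)
        areas = [_polygon_area(self._spline(z)) for z in zz]
        return float(np.trapezoid(areas, zz))


def _polygon_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_centroid(ring: np.ndarray) -> np.ndarray:
    x, y = ring[:, 0], ring[:, 1]
    xr, yr = np.roll(x, -1), np.roll(y, -1)
    cross = x * yr - xr * y
    a = cross.sum() / 2.0
    cx = np.sum((x + xr) * cross) / (6.0 * a)
    cy = np.sum((y + yr) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _resample_ring(poly: np.ndarray, n_theta: int, seam_angle: float
                   ) -> np.ndarray:
    """Arc-length resample of a closed polygon, seam at ``seam_angle``.

    The start point is the vertex whose centroid-relative angle is closest to
    the seam angle; vertex order is made counter-clockwise first.
    """
    x, y = poly[:, 0], poly[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if signed < 0:
        poly = poly[::-1]
    c = _polygon_centroid(poly)
    ang = np.arctan2(poly[:, 1] - c[1], poly[:, 0] - c[0])
    start = int(np.argmin(np.abs(np.angle(np.exp(1j * (ang - seam_angle))))))
    poly = np.roll(poly, -start, axis=0)
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(0, s[-1], n_theta, endpoint=False)
    out = np.empty((n_theta, 2))
    for k in range(2):
        out[:, k] = np.interp(si, s, closed[:, k])
    return out


def _check_simple(ring: np.ndarray) -> bool:
    try:
        from shapely.geometry import Polygon
    except ImportError:  # pragma: no cover
        return True
    return Polygon(ring).is_valid


def loft_outlines(stack: AxialOutlineStack, n_theta: int = 64
                  ) -> tuple[LoftedSurface, LoftedSurface]:
    """Loft the outer and inner outline stacks into surface pairs.

    Raises :class:`MeshingError` with a diagnostic if an input outline or an
    interpolated cross-section self-intersects.
    """
    if len(stack.outlines) < 2:
        raise ValueError("loft undefined for fewer than two slices")

    c0 = _polygon_centroid(stack.outlines[0])
    v0 = stack.outlines[0][0] - c0
    seam = float(np.arctan2(v0[1], v0[0]))

    surfs = []
    for polys in (stack.outlines, stack.inner_outlines):
        rings = []
        for k, poly in enumerate(polys):
            if not _check_simple(poly):
                raise MeshingError(f"outline at slice {k} self-intersects")
            rings.append(_resample_ring(np.asarray(poly, dtype=float),
                                        n_theta, seam))
        surf = LoftedSurface(rings=np.asarray(rings), z=stack.z.copy())
        # probe interpolated cross-sections for loft self-intersection
        for z in np.linspace(stack.z[0], stack.z[-1], 2 * len(polys) + 1):
            if not _check_simple(surf.cross_section(z)):
                raise MeshingError(f"lofted cross-section at z={z:.4f} "
                                   "self-intersects")
        surfs.append(surf)
    return surfs[0], surfs[1]


# --------------------------------------------------------------------------
# swept meshing of the nested solids
# --------------------------------------------------------------------------

def _template_counts(n_theta: int, rings_inner: int, rings_outer: int,
                     n_z: int) -> int:
    n_tri = n_theta * (2 * (rings_inner + rings_outer) - 1)
    return 3 * n_tri * (n_z - 1)


def mesh_solids(outer: LoftedSurface, inner: LoftedSurface,
                target_element_count: int = 5000,
                mediastinal_direction: tuple[float, float] = (-1.0, 0.0),
                mediastinal_cos_threshold: float = 0.5) -> TetMesh:
    """Mesh the nested solids with quadratic tetrahedra.

    A triangulated cross-section template (rings of vertices between the
    centroid, the inner boundary and the outer boundary) is swept along z;
    prisms are split with the min-vertex rule.  The element count lands
    within ~30% of ``target_element_count``.

    Boundary face labels: ``apical`` / ``basal`` on the extreme z planes,
    and the lateral wall split into ``mediastinal`` (outward normal within
    the configured half-space toward the midline) and ``outer-lateral``.
    """
    z0, z1 = outer.z[0], outer.z[-1]
    height = z1 - z0
    r_mean = np.sqrt(_polygon_area(outer.cross_section(0.5 * (z0 + z1))) / np.pi)

    # pick discretization parameters by scanning the edge-length scale
    best = None
    for h in np.geomspace(r_mean / 2, r_mean / 40, 120):
        n_z = max(3, int(round(height / h)) + 1)
        n_th = max(8, int(round(2 * np.pi * r_mean / h)))
        ri = max(2, int(round(0.8 * r_mean / h)))
        ro = max(1, int(round(0.2 * r_mean / h)))
        count = _template_counts(n_th, ri, ro, n_z)
        err = abs(count - target_element_count)
        if best is None or err < best[0]:
            best = (err, n_z, n_th, ri, ro)
    _, n_z, n_theta, rings_inner, rings_outer = best

    zz = np.linspace(z0, z1, n_z)
    # template: center + rings_inner rings up to the inner boundary +
    # rings_outer rings up to the outer boundary
    f_in = np.arange(1, rings_inner + 1) / rings_inner
    f_out = np.arange(1, rings_outer + 1) / rings_outer
    verts_per_level = 1 + (rings_inner + rings_outer) * n_theta

    verts = np.empty((n_z * verts_per_level, 3))
    for lev, z in enumerate(zz):
        ring_in = inner.cross_section(z, n_theta)
        ring_out = outer.cross_section(z, n_theta)
        c = _polygon_centroid(ring_in)
        pts = [c]
        for f in f_in:
            pts.append(c + f * (ring_in - c))
        for f in f_out:
            pts.append(ring_in + f * (ring_out - ring_in))
        level_pts = np.vstack([np.atleast_2d(p) for p in pts])
        base = lev * verts_per_level
        verts[base:base + verts_per_level, :2] = level_pts
        verts[base:base + verts_per_level, 2] = z

    # 2D template triangulation (local indices within one level)
    def ring_idx(r, j):  # r = 1-based ring, j = angular index
        return 1 + (r - 1) * n_theta + (j % n_theta)

    tris = []          # (3 local ids, domain)
    for j in range(n_theta):
        tris.append(((0, ring_idx(1, j), ring_idx(1, j + 1)), 0))
    n_rings = rings_inner + rings_outer
    for r in range(1, n_rings):
        dom = 0 if r < rings_inner else 1
        for j in range(n_theta):
            a, b = ring_idx(r, j), ring_idx(r, j + 1)
            c_, d = ring_idx(r + 1, j), ring_idx(r + 1, j + 1)
            tris.append(((a, b, d), dom))
            tris.append(((a, d, c_), dom))

    prisms = []
    prism_dom = []
    for lev in range(n_z - 1):
        b0 = lev * verts_per_level
        b1 = (lev + 1) * verts_per_level
        for (tri, dom) in tris:
            prisms.append([b0 + tri[0], b0 + tri[1], b0 + tri[2],
                           b1 + tri[0], b1 + tri[1], b1 + tri[2]])
            prism_dom.append(dom)
    prisms = np.asarray(prisms, dtype=np.int64)
    tets = split_prisms(prisms)
    domain = np.repeat(np.asarray(prism_dom, dtype=np.int8), 3)
    tets = _orient_positive(verts, tets)

    vols = np.einsum("ei,ei->e",
                     (verts[tets[:, 1]] - verts[tets[:, 0]]),
                     np.cross(verts[tets[:, 2]] - verts[tets[:, 0]],
                              verts[tets[:, 3]] - verts[tets[:, 0]])) / 6.0
    if np.any(vols <= 0):
        bad = int(np.argmin(vols))
        raise MeshingError(
            f"degenerate element near {verts[tets[bad, 0]]} "
            "(non-star-shaped cross-section?)")

    nodes, conn = _tet4_to_tet10(verts, tets)
    mesh = TetMesh(nodes=nodes, elements=conn, n_vertices=verts.shape[0],
                   domain=domain)

    faces = boundary_faces(conn)
    normals, _ = face_normals_areas(nodes, faces)
    centroids = nodes[faces[:, :3]].mean(axis=1)
    tol = 1e-9 + 1e-6 * height
    apical = centroids[:, 2] > z1 - tol
    basal = centroids[:, 2] < z0 + tol
    lateral = ~(apical | basal)
    d = np.asarray(mediastinal_direction, dtype=float)
    d = d / np.linalg.norm(d)
    med = lateral & (normals[:, :2] @ d > mediastinal_cos_threshold)
    mesh.face_labels = {
        "apical": faces[apical],
        "basal": faces[basal],
        "mediastinal": faces[med],
        "outer-lateral": faces[lateral & ~med],
    }
    return mesh


# --------------------------------------------------------------------------
# stiffness interpolation onto the mesh
# --------------------------------------------------------------------------

@dataclass
class LungSectionModel:
    """Meshed lung section with its nodal shear-modulus field."""

    mesh: TetMesh
    nodal_G: np.ndarray       # Pa per node
    mean_G: float             # Pa, mean over inner nodes
    n_filled_nodes: int = 0   # inner nodes fed by nearest-valid fallback

    def __post_init__(self) -> None:
        if np.any(self.nodal_G <= 0):
            raise ValueError("nodal shear modulus must be positive")


def interpolate_stiffness(mesh: TetMesh,
                          maps: np.ndarray,
                          slice_z: np.ndarray,
                          pixel_spacing: float,
                          valid: np.ndarray | None = None,
                          origin: tuple[float, float] | None = None
                          ) -> LungSectionModel:
    """Map per-slice stiffness images onto mesh nodes.

    Inner-solid nodes take the trilinear interpolation (bilinear in plane,
    linear in z, clamped beyond the extreme slices) of the valid pixels;
    invalid pixels are excluded by nearest-valid filling, and nodes whose
    nearest pixel was itself invalid are counted in ``n_filled_nodes``.
    Nodes used only by the outer shell receive the mean of the interpolated
    inner values, the outer region's assumed homogeneous modulus.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    n_sl, ny, nx = maps.shape
    slice_z = np.asarray(slice_z, dtype=float)
    if valid is None:
        valid = np.isfinite(maps) & (maps > 0)
    if not valid.any():
        raise ValueError("no valid pixels to interpolate")

    if origin is None:
        origin = (-(nx - 1) / 2.0 * pixel_spacing,
                  -(ny - 1) / 2.0 * pixel_spacing)

    filled = np.empty_like(maps)
    was_filled = np.empty_like(valid)
    for k in range(n_sl):
        if valid[k].any():
            idx = ndimage.distance_transform_edt(
                ~valid[k], return_distances=False, return_indices=True)
            filled[k] = maps[k][tuple(idx)]
            was_filled[k] = ~valid[k]
        else:
            pool = maps[valid]
            filled[k] = np.median(pool)
            was_filled[k] = True

    x = origin[0] + np.arange(nx) * pixel_spacing
    y = origin[1] + np.arange(ny) * pixel_spacing
    interp = RegularGridInterpolator((slice_z, y, x), filled,
                                     method="linear", bounds_error=False)
    fill_interp = RegularGridInterpolator((slice_z, y, x),
                                          was_filled.astype(float),
                                          method="nearest", bounds_error=False)

    inner_nodes = np.unique(mesh.elements[mesh.domain == 0])
    pts = mesh.nodes[inner_nodes]
    q = np.column_stack([
        np.clip(pts[:, 2], slice_z[0], slice_z[-1]),
        np.clip(pts[:, 1], y[0], y[-1]),
        np.clip(pts[:, 0], x[0], x[-1]),
    ])
    g_inner = interp(q)
    n_filled = int(np.sum(fill_interp(q) > 0.5))

    nodal_g = np.full(mesh.n_nodes, float(np.mean(g_inner)))
    nodal_g[inner_nodes] = g_inner
    return LungSectionModel(mesh=mesh, nodal_G=nodal_g,
                            mean_G=float(np.mean(g_inner)),
                            n_filled_nodes=n_filled)


def uniform_model(mesh: TetMesh, shear_modulus: float) -> LungSectionModel:
    """Homogeneous-stiffness counterpart of an MRE-based model."""
    if shear_modulus <= 0:
        raise ValueError("shear modulus must be positive")
    g = np.full(mesh.n_nodes, float(shear_modulus))
    return LungSectionModel(mesh=mesh, nodal_G=g, mean_G=float(shear_modulus))
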