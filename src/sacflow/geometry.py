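"""Parametric vessel geometry and graded triangular meshing.

The study domain is a 2D cut through a straight artery segment: a rectangle
``z in [0, L]`` (axial) by ``x in [0, H]`` (transverse), optionally carrying a
circular-arc aneurysmal sac bulging outward from the upper wall, with a
rupture orifice at the sac apex.  The same module builds the analytic
verification domains (plain channel, axisymmetric tube) and a deterministic
graded triangle mesher on top of :class:`scipy.spatial.Delaunay`.

Coordinate convention: node columns are ``(z, x)`` with ``z`` axial and ``x``
transverse (the radius ``r`` in axisymmetric mode); origin at the
inlet / lower-wall corner.

Boundary tags: ``INLET`` (z = 0), ``OUTLET`` (z = L), ``RUPTURE`` (orifice arc
at the sac apex), ``AXIS`` (x = 0 symmetry axis, axisymmetric mode only) and
``WALL`` for everything else.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

__all__ = [
    "GeometryError",
    "MeshingError",
    "VesselGeometry",
    "MeshSizing",
    "Boundary",
    "BoundaryPiece",
    "Mesh",
    "MeshQualityReport",
    "build_geometry",
    "generate_mesh",
    "rectangle_mesh",
    "quality_report",
    "write_mesh",
    "read_mesh",
    "sac_area",
]

INLET, OUTLET, WALL, RUPTURE, AXIS = "INLET", "OUTLET", "WALL", "RUPTURE", "AXIS"
VALID_TAGS = (INLET, OUTLET, WALL, RUPTURE, AXIS)


class GeometryError(ValueError):
    """Invalid or self-intersecting geometric parameters."""


class MeshingError(RuntimeError):
    """Mesh generation failed (degenerate boundary, lost boundary edge, ...)."""


@dataclass(frozen=True)
class VesselGeometry:
    """Parametric vessel-with-sac description (all lengths in metres).

    The sac is a circular disc of radius ``sac_radius`` whose chord on the
    upper wall has length ``neck_width``; the rupture orifice is an arc of
    chordal width ``orifice_width`` centred on the sac apex.
    """

    length: float = 0.7
    height: float = 0.09
    mode: str = "planar"  # planar | axisymmetric
    sac_center_z: float = 0.30
    sac_radius: float = 0.025
    neck_width: float = 0.035
    orifice_width: float = 0.008
    has_sac: bool = True
    has_orifice: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0 or self.height <= 0:
            raise GeometryError("length and height must be positive")
        if self.mode not in ("planar", "axisymmetric"):
            raise GeometryError(f"unknown mode {self.mode!r}")
        if self.has_orifice and not self.has_sac:
            raise GeometryError("rupture orifice requested without a sac")
        if self.mode == "axisymmetric" and self.has_sac:
            raise GeometryError("axisymmetric mode requires has_sac=False "
                                "(the sidewall sac breaks axisymmetry)")
        if self.has_sac:
            if not (0 < self.neck_width < self.length):
                raise GeometryError("neck_width must lie in (0, length)")
            if self.neck_width >= 2 * self.sac_radius:
                raise GeometryError("neck_width must be below the sac diameter")
            half = 0.5 * self.neck_width
            if not (half < self.sac_center_z < self.length - half):
                raise GeometryError("sac neck must sit strictly inside the upper wall")
            if self.has_orifice and self.orifice_width >= self.sac_arc_length:
                raise GeometryError("orifice_width must be below the sac arc length")

    # sac circle centre sits above the upper wall by h0 = sqrt(r^2 - (w/2)^2)
    @property
    def sac_bulge(self) -> float:
        """Stand-off of the sac centre above the upper wall, m."""
        return math.sqrt(self.sac_radius**2 - (0.5 * self.neck_width) ** 2)

    @property
    def sac_center(self) -> tuple[float, float]:
        """(z, x) centre of the sac circle."""
        return (self.sac_center_z, self.height + self.sac_bulge)

    @property
    def sac_arc_length(self) -> float:
        th1, th2 = self._neck_angles()
        return self.sac_radius * (th2 - th1)

    @property
    def orifice_center(self) -> tuple[float, float]:
        """(z, x) midpoint of the rupture orifice (the sac apex)."""
        return (self.sac_center_z, self.height + self.sac_bulge + self.sac_radius)

    def _neck_angles(self) -> tuple[float, float]:
        """Arc angle range (th1 < th2, CCW) of the sac boundary between the
        neck corners, measured about the sac centre."""
        half = 0.5 * self.neck_width
        th1 = math.atan2(-self.sac_bulge, half)          # right neck corner
        th2 = math.atan2(-self.sac_bulge, -half)          # left neck corner
        if th2 < th1:
            th2 += 2 * math.pi
        return th1, th2


def sac_area(sac_radius: float, neck_width: float) -> float:
    """Exact area the sac adds above the upper wall: the major circular
    segment cut by the neck chord."""
    r, c = sac_radius, 0.5 * neck_width
    h0 = math.sqrt(r * r - c * c)
    minor = r * r * math.asin(c / r) - c * h0  # minor segment below the chord
    return math.pi * r * r - minor


@dataclass(frozen=True)
class MeshSizing:
    """Element-size controls (Table-style graded sizing, lengths in metres)."""

    h_max: float = 0.0169
    h_min: float = 0.0032
    growth_rate: float = 1.13
    narrow_resolution: float = 0.8
    curvature_factor: float = 0.06

    def __post_init__(self) -> None:
        if not (0 < self.h_min <= self.h_max):
            raise GeometryError("need 0 < h_min <= h_max")
        if self.growth_rate < 1:
            raise GeometryError("growth_rate must be >= 1")


@dataclass(frozen=True)
class BoundaryPiece:
    """One boundary primitive: a straight segment or a CCW circular arc."""

    kind: str  # "line" | "arc"
    tag: str
    p0: tuple[float, float] = (0.0, 0.0)
    p1: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 0.0
    theta0: float = 0.0
    theta1: float = 0.0

    @property
    def length(self) -> float:
        if self.kind == "line":
            return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])
        return self.radius * (self.theta1 - self.theta0)

    def point(self, s: float) -> tuple[float, float]:
        """Point at arclength fraction s in [0, 1]."""
        if self.kind == "line":
            return (self.p0[0] + s * (self.p1[0] - self.p0[0]),
                    self.p0[1] + s * (self.p1[1] - self.p0[1]))
        th = self.theta0 + s * (self.theta1 - self.theta0)
        return (self.center[0] + self.radius * math.cos(th),
                self.center[1] + self.radius * math.sin(th))


@dataclass(frozen=True)
class Boundary:
    """Closed, CCW-ordered loop of tagged boundary pieces."""

    pieces: tuple[BoundaryPiece, ...]
    params: Optional[VesselGeometry] = None

    def polygon(self, pts_per_arc: int = 256) -> Polygon:
        pts = []
        for pc in self.pieces:
            n = 1 if pc.kind == "line" else pts_per_arc
            for i in range(n):
                pts.append(pc.point(i / n))
        return Polygon(pts)

    @property
    def tags(self) -> set[str]:
        return {pc.tag for pc in self.pieces}


def build_geometry(params: VesselGeometry) -> Boundary:
    """Assemble the tagged boundary loop of the vessel domain.

    The loop runs counterclockwise from the inlet / lower-wall corner so the
    fluid interior is always to its left.
    """
    L, H = params.length, params.height
    bottom_tag = AXIS if params.mode == "axisymmetric" else WALL
    pieces: list[BoundaryPiece] = [
        BoundaryPiece("line", bottom_tag, p0=(0.0, 0.0), p1=(L, 0.0)),
        BoundaryPiece("line", OUTLET, p0=(L, 0.0), p1=(L, H)),
    ]
    if not params.has_sac:
        pieces.append(BoundaryPiece("line", WALL, p0=(L, H), p1=(0.0, H)))
    else:
        zc = params.sac_center_z
        half = 0.5 * params.neck_width
        cz, cx = params.sac_center
        r = params.sac_radius
        th1, th2 = params._neck_angles()
        pieces.append(BoundaryPiece("line", WALL, p0=(L, H), p1=(zc + half, H)))
        if params.has_orifice:
            dth = 0.5 * params.orifice_width / r  # half-angle of the orifice arc
            apex = 0.5 * math.pi
            pieces.append(BoundaryPiece("arc", WALL, center=(cz, cx), radius=r,
                                        theta0=th1, theta1=apex - dth))
            pieces.append(BoundaryPiece("arc", RUPTURE, center=(cz, cx), radius=r,
                                        theta0=apex - dth, theta1=apex + dth))
            pieces.append(BoundaryPiece("arc", WALL, center=(cz, cx), radius=r,
                                        theta0=apex + dth, theta1=th2))
        else:
            pieces.append(BoundaryPiece("arc", WALL, center=(cz, cx), radius=r,
                                        theta0=th1, theta1=th2))
        pieces.append(BoundaryPiece("line", WALL, p0=(zc - half, H), p1=(0.0, H)))
    pieces.append(BoundaryPiece("line", INLET, p0=(0.0, H), p1=(0.0, 0.0)))
    boundary = Boundary(tuple(pieces), params=params)
    if not boundary.polygon().is_valid:
        raise GeometryError("boundary loop is self-intersecting")
    return boundary


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Conforming triangle mesh with tagged boundary edges.

    ``nodes`` has columns (z, x); triangles are CCW vertex index triples;
    each boundary edge carries exactly one tag from :data:`VALID_TAGS`.
    """

    nodes: np.ndarray          # (N, 2) float
    triangles: np.ndarray      # (M, 3) int
    boundary_edges: np.ndarray  # (B, 2) int, ordered along the loop direction
    boundary_tags: np.ndarray  # (B,) of str
    region_id: np.ndarray = field(default=None)  # (M,) int: 0 lumen, 1 sac
    mode: str = "planar"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.boundary_edges = np.asarray(self.boundary_edges, dtype=np.int64)
        self.boundary_tags = np.asarray(self.boundary_tags, dtype=object)
        if self.region_id is None:
            self.region_id = np.zeros(len(self.triangles), dtype=np.int64)
        self.region_id = np.asarray(self.region_id, dtype=np.int64)
        bad = set(self.boundary_tags) - set(VALID_TAGS)
        if bad:
            raise MeshingError(f"unknown boundary tags {sorted(bad)}")
        # enforce positive (CCW) orientation
        a2 = self._signed_areas2()
        flip = a2 < 0
        if flip.any():
            tri = self.triangles.copy()
            tri[flip, 1], tri[flip, 2] = self.triangles[flip, 2], self.triangles[flip, 1]
            self.triangles = tri

    def _signed_areas2(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def areas(self) -> np.ndarray:
        return 0.5 * np.abs(self._signed_areas2())

    def total_area(self) -> float:
        return float(self.areas().sum())

    def edges_by_tag(self, tag: str) -> np.ndarray:
        if tag not in VALID_TAGS:
            raise KeyError(f"unknown boundary tag {tag!r}")
        return self.boundary_edges[self.boundary_tags == tag]

    def check(self) -> None:
        """Structural sanity checks; raises MeshingError on violation."""
        edge_count: dict[tuple[int, int], int] = {}
        for t in self.triangles:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                key = (min(a, b), max(a, b))
                edge_count[key] = edge_count.get(key, 0) + 1
        hull = {e for e, c in edge_count.items() if c == 1}
        tagged = {(min(a, b), max(a, b)) for a, b in self.boundary_edges}
        if hull != tagged:
            raise MeshingError(
                f"boundary tagging incomplete: {len(hull)} hull edges vs "
                f"{len(tagged)} tagged edges")


@dataclass(frozen=True)
class MeshQualityReport:
    n_elements: int
    n_vertices: int
    min_quality: float
    avg_quality: float
    total_area: float


def triangle_quality(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Normalized quality 4*sqrt(3)*area / sum(edge^2); 1 for equilateral."""
    p = nodes[triangles]
    e0 = p[:, 1] - p[:, 0]
    e1 = p[:, 2] - p[:, 1]
    e2 = p[:, 0] - p[:, 2]
    area = 0.5 * np.abs(e0[:, 0] * (-e2[:, 1]) - e0[:, 1] * (-e2[:, 0]))
    ssq = (e0 * e0).sum(1) + (e1 * e1).sum(1) + (e2 * e2).sum(1)
    return 4.0 * math.sqrt(3.0) * area / ssq


def quality_report(mesh: Mesh) -> MeshQualityReport:
    """Element-quality statistics.  Degenerate (zero-area) triangles enter the
    statistics with quality 0 rather than being dropped."""
    q = triangle_quality(mesh.nodes, mesh.triangles)
    return MeshQualityReport(
        n_elements=mesh.n_triangles,
        n_vertices=mesh.n_nodes,
        min_quality=float(q.min()),
        avg_quality=float(q.mean()),
        total_area=mesh.total_area(),
    )


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------

def _size_field(pts: np.ndarray, sizing: MeshSizing,
                refine_center: Optional[np.ndarray], refine_radius: float,
                narrow_cap: float = math.inf) -> np.ndarray:
    """Target edge length at each point: h_min inside the refinement ball,
    growing linearly at (growth_rate - 1) per unit distance outside, capped
    at h_max and at the narrow-region cap."""
    h = np.full(len(pts), min(sizing.h_max, narrow_cap))
    if refine_center is not None:
        d = np.hypot(pts[:, 0] - refine_center[0], pts[:, 1] - refine_center[1])
        local = sizing.h_min + (sizing.growth_rate - 1.0) * np.maximum(d - refine_radius, 0.0)
        h = np.minimum(h, local)
    return np.clip(h, sizing.h_min, sizing.h_max)


def _sample_boundary(boundary: Boundary, sizing: MeshSizing,
                     refine_center, refine_radius, narrow_cap) -> tuple[np.ndarray, np.ndarray]:
    """Discretize the boundary loop at the local target size.

    Returns (points, seg_tags): points (P,2) without repetition of the start
    point; seg_tags[i] tags the segment points[i] -> points[(i+1) % P].
    """
    pts: list[tuple[float, float]] = []
    tags: list[str] = []
    for pc in boundary.pieces:
        h_cap = sizing.h_max
        if pc.kind == "arc":
            # curvature control: chord length <= curvature_factor * radius
            h_cap = min(h_cap, max(sizing.curvature_factor * pc.radius, sizing.h_min))
        mid = np.array([pc.point(0.5)])
        h_loc = _size_field(mid, sizing, refine_center, refine_radius, narrow_cap)[0]
        h_loc = min(h_loc, h_cap)
        # subdivide at the finest size requested anywhere along the piece so
        # graded pieces (e.g. the sac arc through the refinement ball) conform
        probe = np.array([pc.point(s) for s in np.linspace(0.0, 1.0, 17)])
        h_loc = min(h_loc, float(
            _size_field(probe, sizing, refine_center, refine_radius, narrow_cap).min()), h_cap)
        n = max(1, int(math.ceil(pc.length / h_loc)))
        for i in range(n):
            pts.append(pc.point(i / n))
            tags.append(pc.tag)
    return np.array(pts), np.array(tags, dtype=object)


def _point_segment_distance(pts: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray) -> np.ndarray:
    """Min distance from each point to any of the segments (vectorized)."""
    d = seg_b - seg_a                       # (S, 2)
    len2 = (d * d).sum(1)                   # (S,)
    len2[len2 == 0] = 1.0
    best = np.full(len(pts), np.inf)
    # loop over segments (few hundred) with vectorized points
    for a, dd, l2 in zip(seg_a, d, len2):
        t = np.clip(((pts - a) @ dd) / l2, 0.0, 1.0)
        proj = a + t[:, None] * dd
        dist = np.hypot(pts[:, 0] - proj[:, 0], pts[:, 1] - proj[:, 1])
        np.minimum(best, dist, out=best)
    return best


def generate_mesh(boundary: Boundary, sizing: MeshSizing = MeshSizing(),
                  refine_near: Optional[tuple[tuple[float, float], float]] = None,
                  seed: int = 0, smooth_iters: int = 6) -> Mesh:
    """Graded, deterministic triangulation of a tagged boundary loop.

    Interior vertices are seeded on a hexagonal candidate lattice thinned to
    the local target density (fixed ``seed``), then relaxed by Laplacian
    smoothing with Delaunay reconnection.  ``refine_near = ((z, x), radius)``
    forces ``h_min``-sized elements inside the given ball; for a rupture
    geometry it defaults to the orifice midpoint with radius three orifice
    widths.
    """
    params = boundary.params
    if refine_near is None and params is not None and params.has_orifice:
        refine_near = (params.orifice_center, 3.0 * params.orifice_width)
    narrow_cap = math.inf
    if params is not None and params.has_orifice:
        narrow_cap = params.orifice_width / sizing.narrow_resolution
    if refine_near is not None:
        refine_center = np.asarray(refine_near[0], dtype=float)
        refine_radius = float(refine_near[1])
    else:
        refine_center, refine_radius = None, 0.0

    bpts, btags = _sample_boundary(boundary, sizing, refine_center, refine_radius, narrow_cap)
    if len(bpts) < 3:
        raise MeshingError("degenerate boundary: fewer than 3 boundary points")
    poly = Polygon(bpts)
    if not poly.is_valid or poly.area <= 0:
        raise MeshingError("degenerate or self-intersecting boundary polygon")

    # hexagonal candidate lattice at sub-h_min pitch
    a = 0.75 * sizing.h_min
    zmin, xmin, zmax, xmax = poly.bounds
    nz = int((zmax - zmin) / a) + 2
    nx = int((xmax - xmin) / (a * math.sqrt(3) / 2)) + 2
    rows = []
    for j in range(nx):
        x = xmin + j * a * math.sqrt(3) / 2
        off = 0.5 * a if j % 2 else 0.0
        z = zmin + off + a * np.arange(nz)
        rows.append(np.column_stack([z, np.full(nz, x)]))
    cand = np.vstack(rows)
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
    cand = cand[inside]
    seg_a = bpts
    seg_b = np.roll(bpts, -1, axis=0)
    dist_b = _point_segment_distance(cand, seg_a, seg_b)
    h_cand = _size_field(cand, sizing, refine_center, refine_radius, narrow_cap)
    cand = cand[dist_b > 0.55 * h_cand]
    h_cand = _size_field(cand, sizing, refine_center, refine_radius, narrow_cap)
    keep_p = np.minimum((a / h_cand) ** 2, 1.0)
    rng = np.random.default_rng(seed)
    interior = cand[rng.random(len(cand)) < keep_p]

    pts = np.vstack([bpts, interior])
    n_b = len(bpts)

    def triangulate(p):
        tri = Delaunay(p).simplices
        cent = p[tri].mean(axis=1)
        keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        return tri[keep]

    tris = triangulate(pts)
    for _ in range(smooth_iters):
        # Laplacian smoothing of interior points over current connectivity
        nbr_sum = np.zeros_like(pts)
        nbr_cnt = np.zeros(len(pts))
        for i in range(3):
            j = (i + 1) % 3
            np.add.at(nbr_sum, tris[:, i], pts[tris[:, j]])
            np.add.at(nbr_sum, tris[:, j], pts[tris[:, i]])
            np.add.at(nbr_cnt, tris[:, i], 1)
            np.add.at(nbr_cnt, tris[:, j], 1)
        mask = nbr_cnt > 0
        new = pts.copy()
        new[mask] = nbr_sum[mask] / nbr_cnt[mask, None]
        new[:n_b] = bpts  # boundary fixed
        # keep interior points inside
        ok = shapely.contains_xy(poly, new[n_b:, 0], new[n_b:, 1])
        new[n_b:][~ok] = pts[n_b:][~ok]
        pts = new
        tris = triangulate(pts)

    # drop unused points (rare isolated candidates)
    used = np.zeros(len(pts), dtype=bool)
    used[tris.ravel()] = True
    if not used[:n_b].all():
        raise MeshingError("mesh generation lost boundary vertices")
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(used.sum())
    pts = pts[used]
    tris = remap[tris]

    # boundary edges: hull edges of the kept triangulation
    edge_count: dict[tuple[int, int], int] = {}
    for t in tris:
        for u, v in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            key = (min(u, v), max(u, v))
            edge_count[key] = edge_count.get(key, 0) + 1
    hull = [e for e, c in edge_count.items() if c == 1]
    expected = {(min(i, (i + 1) % n_b), max(i, (i + 1) % n_b)): btags[i]
                for i in range(n_b)}
    bedges, tags = [], []
    for u, v in hull:
        if (u, v) not in expected:
            raise MeshingError(
                f"triangulation does not conform to the boundary near nodes {u},{v}")
        # restore the CCW loop orientation (consecutive polyline indices)
        if v == u + 1:
            bedges.append((u, v))
        else:  # wrap-around edge (n_b - 1, 0)
            bedges.append((v, u))
        tags.append(expected[(u, v)])
    if len(bedges) != n_b:
        raise MeshingError("boundary loop incomplete after triangulation")

    region = np.zeros(len(tris), dtype=np.int64)
    if params is not None and params.has_sac:
        cent = pts[tris].mean(axis=1)
        region[cent[:, 1] > params.height] = 1
    mode = params.mode if params is not None else "planar"
    mesh = Mesh(pts, tris, np.array(bedges), np.array(tags, dtype=object),
                region_id=region, mode=mode)
    mesh.check()
    return mesh


def rectangle_mesh(length: float, height: float, nz: int, nx: int,
                   mode: str = "planar") -> Mesh:
    """Structured rectangle mesh with alternating diagonals (symmetric under
    x -> H - x).  Left edge INLET, right OUTLET, top WALL, bottom WALL or
    AXIS in axisymmetric mode."""
    z = np.linspace(0.0, length, nz + 1)
    x = np.linspace(0.0, height, nx + 1)
    Z, X = np.meshgrid(z, x, indexing="ij")
    nodes = np.column_stack([Z.ravel(), X.ravel()])

    def nid(i, j):
        return i * (nx + 1) + j

    tris = []
    for i in range(nz):
        for j in range(nx):
            v00, v10 = nid(i, j), nid(i + 1, j)
            v01, v11 = nid(i, j + 1), nid(i + 1, j + 1)
            if (i + j) % 2 == 0:
                tris.append((v00, v10, v11))
                tris.append((v00, v11, v01))
            else:
                tris.append((v00, v10, v01))
                tris.append((v10, v11, v01))
    bedges, tags = [], []
    bottom_tag = AXIS if mode == "axisymmetric" else WALL
    for i in range(nz):
        bedges.append((nid(i, 0), nid(i + 1, 0)))
        tags.append(bottom_tag)
        bedges.append((nid(i + 1, nx), nid(i, nx)))
        tags.append(WALL)
    for j in range(nx):
        bedges.append((nid(0, j + 1), nid(0, j)))
        tags.append(INLET)
        bedges.append((nid(nz, j), nid(nz, j + 1)))
        tags.append(OUTLET)
    mesh = Mesh(nodes, np.array(tris), np.array(bedges),
                np.array(tags, dtype=object), mode=mode)
    mesh.check()
    return mesh


# ---------------------------------------------------------------------------
# Mesh I/O: Gmsh MSH 2.2 ASCII with physical groups as boundary tags
# ---------------------------------------------------------------------------

_TAG_IDS = {t: i + 1 for i, t in enumerate(VALID_TAGS)}
_REGION_BASE = 100  # physical surface id = 100 + region_id


def write_mesh(mesh: Mesh, path) -> None:
    """Write a mesh in Gmsh MSH 2.2 ASCII; boundary tags become 1D physical
    groups, lumen/sac regions become 2D physical groups."""
    path = str(path)
    if not path.endswith(".msh"):
        raise ValueError(f"unknown mesh format for {path!r} (expected .msh)")
    used_tags = sorted(set(mesh.boundary_tags), key=list(VALID_TAGS).index)
    regions = sorted(set(mesh.region_id.tolist()))
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(used_tags) + len(regions) + 1)]
    for t in used_tags:
        lines.append(f'1 {_TAG_IDS[t]} "{t}"')
    for r in regions:
        lines.append(f'2 {_REGION_BASE + r} "region{r}"')
    lines.append(f'0 999 "mode:{mesh.mode}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (zc, xc) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {float(zc)!r} {float(xc)!r} 0")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(len(mesh.boundary_edges) + mesh.n_triangles))
    eid = 1
    for (u, v), t in zip(mesh.boundary_edges, mesh.boundary_tags):
        lines.append(f"{eid} 1 2 {_TAG_IDS[t]} 0 {u + 1} {v + 1}")
        eid += 1
    for t, r in zip(mesh.triangles, mesh.region_id):
        lines.append(f"{eid} 2 2 {_REGION_BASE + r} 0 {t[0] + 1} {t[1] + 1} {t[2] + 1}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mesh(path) -> Mesh:
    """Read a Gmsh MSH 2.2 ASCII mesh written by :func:`write_mesh` (or any
    MSH2 file whose 1D physical names match the tag vocabulary)."""
    path = str(path)
    if not path.endswith(".msh"):
        raise ValueError(f"unknown mesh format for {path!r} (expected .msh)")
    with open(path) as fh:
        tokens = fh.read().split("\n")
    sections: dict[str, list[str]] = {}
    cur = None
    for line in tokens:
        s = line.strip()
        if s.startswith("$End"):
            cur = None
        elif s.startswith("$"):
            cur = s[1:]
            sections[cur] = []
        elif cur:
            sections[cur].append(s)
    if "Nodes" not in sections or "Elements" not in sections:
        raise ValueError("not a MSH2 mesh: missing $Nodes/$Elements")
    phys_names: dict[int, tuple[int, str]] = {}
    mode = "planar"
    for line in sections.get("PhysicalNames", [])[1:]:
        parts = line.split(" ", 2)
        if len(parts) < 3:
            continue
        dim, pid, name = int(parts[0]), int(parts[1]), parts[2].strip('"')
        if name.startswith("mode:"):
            mode = name.split(":", 1)[1]
        else:
            phys_names[pid] = (dim, name)
    node_lines = sections["Nodes"][1:]
    nodes = np.empty((len(node_lines), 2))
    for line in node_lines:
        parts = line.split()
        nodes[int(parts[0]) - 1] = (float(parts[1]), float(parts[2]))
    tris, regions, bedges, btags = [], [], [], []
    for line in sections["Elements"][1:]:
        parts = [int(p) for p in line.split()]
        etype, ntags = parts[1], parts[2]
        phys = parts[3] if ntags >= 1 else 0
        conn = parts[3 + ntags:]
        if etype == 1:
            if phys not in phys_names:
                raise ValueError("mesh file lacks boundary tag data for an edge")
            bedges.append((conn[0] - 1, conn[1] - 1))
            btags.append(phys_names[phys][1])
        elif etype == 2:
            tris.append([c - 1 for c in conn])
            regions.append(phys - _REGION_BASE if phys >= _REGION_BASE else 0)
    if not bedges:
        raise ValueError("mesh file contains no tagged boundary edges")
    mesh = Mesh(nodes, np.array(tris), np.array(bedges),
                np.array(btags, dtype=object), region_id=np.array(regions), mode=mode)
    mesh.check()
    return mesh
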