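"""Triangle-mesh data model, I/O and primitive geometric measures.

All coordinates are interpreted as millimetres.  The central object is
:class:`TriSurfaceMesh`, a sanitized 2-manifold triangle surface that is
either closed (test solids) or carries one or more open boundary loops
(aneurysm domes cut free from the parent vasculature).  Heavy lifting for
file formats and convex hulls is delegated to :mod:`trimesh`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: merge tolerance for duplicate vertices, in mm
MERGE_TOL = 1e-9


class MeshError(ValueError):
    """Raised for malformed or unusable input meshes."""


class TriSurfaceMesh:
    """Sanitized triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Vertex indices; each face must reference three distinct,
        in-range vertices.
    sanitize : bool
        Merge duplicate vertices (at :data:`MERGE_TOL`), drop degenerate
        faces, unify winding and orient normals outward.
    """

    def __init__(self, vertices, faces, sanitize: bool = True):
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise MeshError("mesh is not purely triangulated")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise MeshError("invalid face index: face references a missing vertex")
        if sanitize:
            vertices, faces = _sanitize(vertices, faces)
        self._tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        _check_manifold(self._tm)
        self._boundary_loops: list[np.ndarray] | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def vertices(self) -> np.ndarray:
        return self._tm.vertices.view(np.ndarray)

    @property
    def faces(self) -> np.ndarray:
        return self._tm.faces.view(np.ndarray)

    @property
    def face_normals(self) -> np.ndarray:
        return self._tm.face_normals.view(np.ndarray)

    @property
    def face_areas(self) -> np.ndarray:
        return self._tm.area_faces.view(np.ndarray)

    @property
    def vertex_normals(self) -> np.ndarray:
        return self._tm.vertex_normals.view(np.ndarray)

    @property
    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area weights: one third of incident face areas (mm^2)."""
        w = np.zeros(len(self.vertices))
        np.add.at(w, self.faces.ravel(), np.repeat(self.face_areas / 3.0, 3))
        return w

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return self._tm.copy()

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, sanitize: bool = True) -> "TriSurfaceMesh":
        return cls(tm.vertices, tm.faces, sanitize=sanitize)

    # -- boundary topology -------------------------------------------------
    @property
    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex-index loops of the open boundary.

        Each loop follows the direction of the boundary half-edges, i.e. is
        consistent with the surface winding (counter-clockwise when seen
        from outside along the outward normals).
        """
        if self._boundary_loops is None:
            self._boundary_loops = _boundary_loops(self.faces)
        return self._boundary_loops

    @property
    def is_closed(self) -> bool:
        return len(self.boundary_loops) == 0

    # -- I/O -----------------------------------------------------------------
    def save(self, path) -> None:
        self._tm.export(str(path))

    def transformed(self, rotation=None, translation=None, scale=1.0) -> "TriSurfaceMesh":
        """Return a rigidly moved and/or isotropically scaled copy."""
        v = self.vertices * float(scale)
        if rotation is not None:
            v = v @ np.asarray(rotation).T
        if translation is not None:
            v = v + np.asarray(translation)
        return TriSurfaceMesh(v, self.faces, sanitize=False)


@dataclass(frozen=True)
class NeckContour:
    """Closed boundary polyline at the neck (cut line)."""

    points: np.ndarray  # (k, 3); logically closed, first point not repeated
    vertex_indices: np.ndarray = field(default=None, repr=False)

    @property
    def perimeter(self) -> float:
        p = self.points
        return float(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())

    def __post_init__(self):
        if len(self.points) < 3:
            raise MeshError("neck contour needs at least 3 points")
        if self.perimeter <= 0:
            raise MeshError("neck contour has zero perimeter")


@dataclass(frozen=True)
class OstiumPlane:
    """Best-fit reference plane of the neck contour.

    ``normal`` is a unit vector oriented toward the dome.  ``area`` is the
    ostium area S_n (projection of the contour onto the plane), ``perimeter``
    is the contour perimeter P_n, and the characteristic neck diameter is
    D_n = 4 S_n / P_n.
    """

    point: np.ndarray
    normal: np.ndarray
    area: float
    perimeter: float

    def __post_init__(self):
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-12:
            raise MeshError("plane normal must be a unit vector")
        if self.area <= 0:
            raise MeshError("ostium area must be positive")

    @property
    def neck_diameter(self) -> float:
        return 4.0 * self.area / self.perimeter

    def signed_distance(self, points) -> np.ndarray:
        return np.asarray(points - self.point) @ self.normal


# ---------------------------------------------------------------------------
# sanitization helpers
# ---------------------------------------------------------------------------

def _sanitize(vertices: np.ndarray, faces: np.ndarray):
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=9)
    tm.update_faces(tm.nondegenerate_faces(height=1e-12))
    # drop faces with repeated vertex indices after merging
    f = tm.faces
    distinct = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    tm.update_faces(distinct)
    tm.remove_unreferenced_vertices()
    if len(tm.faces) == 0:
        raise MeshError("no valid triangles after sanitization")
    trimesh.repair.fix_normals(tm)
    # for open surfaces fix_normals only unifies winding; flip globally if the
    # normals point inward on average
    centroid = tm.vertices.mean(axis=0)
    outward = ((tm.triangles_center - centroid) * tm.face_normals).sum()
    if outward < 0:
        tm.invert()
    return tm.vertices.view(np.ndarray), tm.faces.view(np.ndarray)


def _check_manifold(tm: trimesh.Trimesh) -> None:
    edges = np.sort(tm.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if counts.size and counts.max() > 2:
        raise MeshError(
            "non-manifold edges beyond repair: %d edges bound >2 faces"
            % int((counts > 2).sum())
        )


def _boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    # boundary half-edges appear exactly once among directed face edges
    directed = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    key = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = directed[counts[inverse] == 1]
    succ = {int(a): int(b) for a, b in boundary}
    loops = []
    visited: set[int] = set()
    for start in sorted(succ):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        nxt = succ.get(start)
        while nxt is not None and nxt != start:
            loop.append(nxt)
            visited.add(nxt)
            nxt = succ.get(nxt)
        if nxt == start and len(loop) >= 3:
            loops.append(np.asarray(loop, dtype=np.int64))
    return loops


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_mesh(path, file_format: str = "auto") -> TriSurfaceMesh:
    """Load and sanitize a triangle mesh from STL/PLY/OBJ."""
    path = Path(path)
    if not path.exists():
        raise MeshError(f"file not found: {path}")
    kwargs = {} if file_format == "auto" else {"file_type": file_format}
    try:
        tm = trimesh.load(str(path), force="mesh", process=False, **kwargs)
    except Exception as exc:  # noqa: BLE001 - surface parser errors verbatim
        raise MeshError(f"unreadable mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshError(f"file {path} does not contain a triangle mesh")
    if tm.faces.shape[1] != 3:
        raise MeshError("mesh is not purely triangulated")
    return TriSurfaceMesh(tm.vertices, tm.faces)


def surface_area(mesh: TriSurfaceMesh) -> float:
    """Total triangle area (mm^2); excludes the open neck by construction."""
    return float(mesh.face_areas.sum())


def enclosed_volume(mesh: TriSurfaceMesh, closure: OstiumPlane | None = None) -> float:
    """Volume (mm^3) enclosed by the surface.

    Closed meshes are integrated directly with the divergence theorem.  Open
    domes require a neck plane ``closure``; the boundary loop is capped by a
    triangle fan against the centroid of its projection onto the plane, which
    is exact for star-shaped neck contours and fails loudly otherwise.
    """
    if mesh.is_closed:
        return float(abs(mesh.to_trimesh().volume))
    if closure is None:
        raise MeshError("open mesh: a neck-plane closure is required for volume")
    contour = extract_neck(mesh)
    cap_vertices, cap_faces = _cap_fan(contour, closure)
    v = np.vstack([mesh.vertices, cap_vertices])
    f = np.vstack([mesh.faces, cap_faces + mesh.n_vertices])
    tm = trimesh.Trimesh(vertices=v, faces=f, process=True)
    if not tm.is_volume:
        trimesh.repair.fix_normals(tm)
    return float(abs(tm.volume))


def _cap_fan(contour: NeckContour, plane: OstiumPlane):
    """Fan-triangulate the neck loop against its projected centroid."""
    pts = contour.points
    proj = pts - np.outer(plane.signed_distance(pts), plane.normal)
    centroid = proj.mean(axis=0)
    e1, e2 = _plane_basis(plane.normal)
    uv = (proj - centroid) @ np.column_stack([e1, e2])
    nxt = np.roll(uv, -1, axis=0)
    cross = uv[:, 0] * nxt[:, 1] - uv[:, 1] * nxt[:, 0]
    if not (np.all(cross > 0) or np.all(cross < 0)):
        raise MeshError(
            "neck contour is not star-shaped w.r.t. its centroid; cannot cap"
        )
    k = len(pts)
    idx = np.arange(k)
    faces = np.column_stack([np.full(k, k), np.roll(idx, -1), idx])
    return np.vstack([pts, centroid]), faces


def _plane_basis(normal: np.ndarray):
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def convex_hull(mesh: TriSurfaceMesh) -> TriSurfaceMesh:
    """Closed convex hull of the vertex set."""
    pts = mesh.vertices
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 3:
        raise MeshError("degenerate (coplanar) input: convex hull is not a solid")
    hull = trimesh.convex.convex_hull(pts)
    return TriSurfaceMesh(hull.vertices, hull.faces, sanitize=False)


def min_bounding_sphere(points) -> tuple[np.ndarray, float]:
    """Minimum enclosing sphere of a point set: (center, radius).

    Uses trimesh's hull-based solver; degenerate inputs (fewer than four
    points, collinear or coplanar sets) fall back to Welzl's algorithm.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.size == 0:
        raise MeshError("empty point set")
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    if len(pts) >= 4:
        try:
            center, radius = trimesh.nsphere.minimum_nsphere(pts)
            return np.asarray(center), float(radius)
        except Exception:  # pragma: no cover - qhull degenerate input
            pass
    return _welzl(pts)


def _circumsphere(support: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Smallest sphere through up to four affinely independent points."""
    if not support:
        return np.zeros(3), 0.0
    p0 = support[0]
    if len(support) == 1:
        return p0.copy(), 0.0
    a = np.asarray(support[1:]) - p0
    rhs = 0.5 * np.einsum("ij,ij->i", a, a)
    # least-norm solution keeps the center in the affine hull of the support
    sol, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    return p0 + sol, float(np.linalg.norm(sol))


def _welzl(pts: np.ndarray) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(0)
    order = rng.permutation(len(pts))

    def mb(n: int, support: list[np.ndarray]) -> tuple[np.ndarray, float]:
        c, r = _circumsphere(support)
        if len(support) == 4:
            return c, r
        for i in range(n):
            p = pts[order[i]]
            if np.linalg.norm(p - c) > r * (1 + 1e-12) + 1e-15:
                c, r = mb(i, support + [p])
        return c, r

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(pts) * 8 + 100))
    try:
        return mb(len(pts), [])
    finally:
        sys.setrecursionlimit(old)


def extract_neck(mesh: TriSurfaceMesh) -> NeckContour:
    """Longest boundary loop of a cut dome, ordered with the surface winding."""
    loops = mesh.boundary_loops
    if not loops:
        raise MeshError("no boundary loop: mesh is closed")
    perims = [
        float(np.linalg.norm(np.roll(mesh.vertices[l], -1, axis=0) - mesh.vertices[l], axis=1).sum())
        for l in loops
    ]
    order = int(np.argmax(perims))
    if len(loops) > 1:
        log.warning(
            "mesh has %d boundary loops; using the longest (perimeter %.3f mm) as neck",
            len(loops), perims[order],
        )
    idx = loops[order]
    return NeckContour(points=mesh.vertices[idx].copy(), vertex_indices=idx)


def fit_neck_plane(contour: NeckContour, mesh: TriSurfaceMesh) -> OstiumPlane:
    """Total-least-squares plane through the cut line.

    The plane normal is oriented toward the dome centroid; the ostium area
    S_n is the area of the contour projected onto the plane.
    """
    pts = contour.points
    center = pts.mean(axis=0)
    centered = pts - center
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise MeshError("collinear neck contour: no unique plane")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    # orient toward the dome
    if (mesh.vertices.mean(axis=0) - center) @ normal < 0:
        normal = -normal
    e1, e2 = _plane_basis(normal)
    uv = centered @ np.column_stack([e1, e2])
    nxt = np.roll(uv, -1, axis=0)
    area = 0.5 * abs(float(np.sum(uv[:, 0] * nxt[:, 1] - uv[:, 1] * nxt[:, 0])))
    return OstiumPlane(point=center, normal=normal, area=area, perimeter=contour.perimeter)
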