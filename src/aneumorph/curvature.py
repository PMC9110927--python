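"""Discrete per-vertex curvature and the 8 curvature-based indices.

Gaussian curvature is estimated by the angle deficit divided by the mixed
vertex area; mean curvature by the magnitude of the cotangent-Laplacian
mean-curvature normal, signed by its alignment with the outward vertex
normal (positive for convex regions).  Boundary vertices are flagged and
excluded from every aggregation: the angle deficit is meaningless there.

The aggregate indices are normalized so that both total-curvature norms
equal 1 on a sphere of any radius:

    GLN  = (1/4pi) * sum |K_G| A          (Gauss-Bonnet calibration)
    MLN  = sum |K_M| A / sqrt(4 pi S)

NGLN/NMLN restrict the same sums to vertices of negative curvature,
GLN_CH/MLN_CH divide by the corresponding totals of the convex hull, and
GH/MH are area-weighted Shannon entropies of the curvature histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh import MeshError, TriSurfaceMesh, convex_hull

log = logging.getLogger(__name__)

#: histogram bins for curvature/writhe entropies
ENTROPY_BINS = 30


@dataclass(frozen=True)
class CurvatureField:
    gaussian: np.ndarray       # per-vertex K_G, mm^-2
    mean: np.ndarray           # per-vertex K_M, mm^-1
    vertex_areas: np.ndarray   # mixed areas, mm^2 (sum equals S exactly)
    boundary_mask: np.ndarray  # True where the estimate is unreliable


@dataclass(frozen=True)
class CurvatureIndices:
    GLN: float
    MLN: float
    NGLN: float
    NMLN: float
    GLN_CH: float
    MLN_CH: float
    GH: float
    MH: float


def _corner_angles_and_cotans(v, f):
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    e0, e1, e2 = p2 - p1, p0 - p2, p1 - p0  # edge opposite each corner
    # angle at corner i is between the two edges incident there
    def angle(a, b):
        cosv = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        return np.arccos(np.clip(cosv, -1.0, 1.0))

    ang = np.stack([angle(-e2, e1), angle(-e0, e2), angle(-e1, e0)], axis=1)
    cot = 1.0 / np.tan(np.clip(ang, 1e-12, np.pi - 1e-12))
    sq = np.stack(
        [np.sum(e0 * e0, axis=1), np.sum(e1 * e1, axis=1), np.sum(e2 * e2, axis=1)],
        axis=1,
    )  # squared length of the edge opposite each corner
    return ang, cot, sq


def _mixed_areas(mesh: TriSurfaceMesh, ang, cot, sq):
    """Meyer et al. mixed Voronoi areas with the obtuse-triangle clamp."""
    f = mesh.faces
    fa = mesh.face_areas
    n_obtuse = 0
    areas = np.zeros(mesh.n_vertices)
    obtuse = ang.max(axis=1) > np.pi / 2 + 1e-12
    n_obtuse = int(obtuse.sum())
    # non-obtuse: Voronoi area at corner i = 1/8 (|e_j|^2 cot(ang_j) + |e_k|^2 cot(ang_k))
    vor = np.empty_like(ang)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        vor[:, i] = (sq[:, j] * cot[:, j] + sq[:, k] * cot[:, k]) / 8.0
    clamp = np.empty_like(ang)
    at_obtuse = ang > np.pi / 2 + 1e-12
    clamp[:] = fa[:, None] / 4.0
    clamp[at_obtuse] = np.repeat(fa, 3).reshape(-1, 3)[at_obtuse] / 2.0
    contrib = np.where(obtuse[:, None], clamp, vor)
    np.add.at(areas, f.ravel(), contrib.ravel())
    if n_obtuse:
        log.debug("mixed-area clamp applied to %d obtuse triangles", n_obtuse)
    return areas


def estimate_curvature(mesh: TriSurfaceMesh) -> CurvatureField:
    v, f = mesh.vertices, mesh.faces
    ang, cot, sq = _corner_angles_and_cotans(v, f)
    areas = _mixed_areas(mesh, ang, cot, sq)

    # Gaussian: angle deficit / mixed area
    angle_sum = np.zeros(mesh.n_vertices)
    np.add.at(angle_sum, f.ravel(), ang.ravel())
    boundary = np.zeros(mesh.n_vertices, dtype=bool)
    for loop in mesh.boundary_loops:
        boundary[loop] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        k_g = np.where(areas > 0, (2.0 * np.pi - angle_sum) / areas, 0.0)

    # mean: cotangent Laplacian; Delta x = 2 K_M n_inward
    lap = np.zeros_like(v)
    wsum_at = np.zeros(mesh.n_vertices)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        w = cot[:, i]  # cot at corner i weights edge (j, k)
        for a, b in ((j, k), (k, j)):
            np.add.at(lap, f[:, a], w[:, None] * (v[f[:, a]] - v[f[:, b]]))
    with np.errstate(divide="ignore", invalid="ignore"):
        hvec = lap / (2.0 * areas[:, None])
    hmag = 0.5 * np.linalg.norm(hvec, axis=1)
    # hvec = sum w (x_i - x_j): points outward (along the normal) on a
    # convex surface, where mean curvature is positive
    sign = np.where(np.einsum("ij,ij->i", hvec, mesh.vertex_normals) >= 0, 1.0, -1.0)
    k_m = sign * hmag
    k_g[boundary] = 0.0
    k_m[boundary] = 0.0
    if not np.all(np.isfinite(k_g[~boundary])) or not np.all(np.isfinite(k_m[~boundary])):
        raise MeshError("non-finite curvature at interior vertices")
    return CurvatureField(gaussian=k_g, mean=k_m, vertex_areas=areas, boundary_mask=boundary)


def weighted_entropy(values: np.ndarray, weights: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    """Shannon entropy (nats) of an area-weighted equal-width histogram."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or weights.sum() <= 0:
        return 0.0
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi)):
        return 0.0
    hist, _ = np.histogram(values, bins=bins, range=(lo, hi), weights=weights)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _totals(field: CurvatureField):
    m = ~field.boundary_mask
    a = field.vertex_areas[m]
    kg, km = field.gaussian[m], field.mean[m]
    s = a.sum()
    return {
        "abs_g": float(np.sum(np.abs(kg) * a)),
        "abs_m": float(np.sum(np.abs(km) * a)),
        "neg_g": float(np.sum(np.abs(kg[kg < 0]) * a[kg < 0])),
        "neg_m": float(np.sum(np.abs(km[km < 0]) * a[km < 0])),
        "S": float(s),
    }


def curvature_indices(
    field: CurvatureField,
    mesh: TriSurfaceMesh,
    hull: TriSurfaceMesh | None = None,
    hull_field: CurvatureField | None = None,
) -> CurvatureIndices:
    """Aggregate a curvature field into the 8 indices.

    For open domes the hull closes the neck with a flat facet whose rim
    concentrates spurious curvature; hull vertices coinciding with boundary
    vertices of the input mesh are therefore excluded from the hull totals,
    so that GLN_CH is 1 for a convex dome.
    """
    if hull is None:
        hull = convex_hull(mesh)
    if hull_field is None:
        hull_field = estimate_curvature(hull)
    hmask = ~hull_field.boundary_mask
    if not mesh.is_closed:
        bset = {tuple(np.round(p, 9)) for l in mesh.boundary_loops for p in mesh.vertices[l]}
        on_rim = np.array(
            [tuple(np.round(p, 9)) in bset for p in hull.vertices], dtype=bool
        )
        hmask &= ~on_rim
    ha = hull_field.vertex_areas[hmask]
    t = _totals(field)
    hull_abs_g = float(np.sum(np.abs(hull_field.gaussian[hmask]) * ha))
    hull_abs_m = float(np.sum(np.abs(hull_field.mean[hmask]) * ha))
    if hull_abs_g <= 0 or hull_abs_m <= 0:
        raise MeshError("degenerate hull: zero total curvature")
    norm_g = 1.0 / (4.0 * np.pi)
    norm_m = 1.0 / np.sqrt(4.0 * np.pi * t["S"])
    m = ~field.boundary_mask
    return CurvatureIndices(
        GLN=norm_g * t["abs_g"],
        MLN=norm_m * t["abs_m"],
        NGLN=norm_g * t["neg_g"],
        NMLN=norm_m * t["neg_m"],
        GLN_CH=t["abs_g"] / hull_abs_g,
        MLN_CH=(t["abs_m"] / np.sqrt(t["S"])) / (hull_abs_m / np.sqrt(ha.sum())),
        GH=weighted_entropy(field.gaussian[m], field.vertex_areas[m]),
        MH=weighted_entropy(field.mean[m], field.vertex_areas[m]),
    )
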