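"""The 12 geometry indices for dome-type cuts: 6 size, 6 shape.

Size indices (mm-based): dome volume V, dome surface area S (neck opening
excluded), neck diameter D_n = 4 S_n / P_n, maximum cross-section diameter
D_max, height H and aneurysm size aSz (minimum-bounding-sphere diameter).

Shape indices (dimensionless): aspect ratio AR = H/D_n, bottleneck factor
BF = D_max/D_n, conicity CP = 0.5 - H_Dmax/H, non-sphericity
NSI = 1 - (18 pi)^(1/3) V^(2/3) / S (zero for an ideal half-sphere),
ellipticity EI (NSI evaluated on the convex hull) and undulation
UI = 1 - V/V_CH (zero for convex domes).

These indices are defined only for cuts that isolate the dome itself
(*dome* and *ninja*); calling them on *cut1*/*cut2* meshes is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .mesh import (
    MeshError,
    OstiumPlane,
    TriSurfaceMesh,
    _plane_basis,
    convex_hull,
    enclosed_volume,
    min_bounding_sphere,
    surface_area,
)

SPHERE_CONST = (18.0 * np.pi) ** (1.0 / 3.0)

#: default number of cross-sections for the D_max search
N_SLICES = 100


@dataclass(frozen=True)
class SizeIndices:
    V: float      # mm^3
    S: float      # mm^2
    Dn: float     # mm
    Dmax: float   # mm
    H: float      # mm
    aSz: float    # mm
    H_Dmax: float = float("nan")  # height of the maximizing section, for CP


@dataclass(frozen=True)
class ShapeIndices:
    AR: float
    BF: float
    CP: float
    NSI: float
    EI: float
    UI: float


def _check_cut_type(cut_type: str) -> None:
    if cut_type not in ("dome", "ninja"):
        raise MeshError(
            f"geometry indices are defined only for dome-type cuts, not {cut_type!r}"
        )


def cross_sections(
    mesh: TriSurfaceMesh, plane: OstiumPlane, n_slices: int = N_SLICES
):
    """Characteristic diameter 4A/P of cross-sections parallel to the neck.

    Returns (heights, diameters) for ``n_slices`` sections placed at the
    midpoints of a uniform partition of (0, H].  Sections may consist of
    several loops (blebs); area and perimeter are summed over loops.
    """
    heights_v = plane.signed_distance(mesh.vertices)
    h_max = float(heights_v.max())
    if h_max <= 0:
        raise MeshError("all vertices on or below the neck plane")
    heights = (np.arange(n_slices) + 0.5) / n_slices * h_max
    tm = mesh.to_trimesh()
    lines, to_3d, face_idx = trimesh.intersections.mesh_multiplane(
        tm, plane_origin=plane.point, plane_normal=plane.normal, heights=heights
    )
    face_normals = mesh.face_normals
    diam = np.zeros(n_slices)
    for i in range(n_slices):
        seg = lines[i]
        if len(seg) == 0:
            continue
        basis = to_3d[i][:3, :2]  # columns: in-plane basis vectors
        m2 = face_normals[face_idx[i]] @ basis  # projected face normals, 2D
        p0, p1 = seg[:, 0, :], seg[:, 1, :]
        u = p1 - p0
        # orient segments so the section boundary runs counter-clockwise:
        # cross(projected outward normal, direction) must be positive
        flip = (m2[:, 0] * u[:, 1] - m2[:, 1] * u[:, 0]) < 0
        p0f = np.where(flip[:, None], p1, p0)
        p1f = np.where(flip[:, None], p0, p1)
        area = 0.5 * float(np.sum(p0f[:, 0] * p1f[:, 1] - p1f[:, 0] * p0f[:, 1]))
        perim = float(np.linalg.norm(u, axis=1).sum())
        if perim > 0 and area > 0:
            diam[i] = 4.0 * area / perim
    return heights, diam


def compute_size_indices(
    mesh: TriSurfaceMesh,
    plane: OstiumPlane,
    cut_type: str = "dome",
    n_slices: int = N_SLICES,
) -> SizeIndices:
    _check_cut_type(cut_type)
    S = surface_area(mesh)
    V = enclosed_volume(mesh, plane)
    heights_v = plane.signed_distance(mesh.vertices)
    H = float(heights_v.max())
    if H <= 0:
        raise MeshError("all vertices on or below the neck plane")
    heights, diam = cross_sections(mesh, plane, n_slices=n_slices)
    # lowest slice wins ties (within 1e-9) so CP is maximal and deterministic
    best = diam.max()
    i_best = int(np.flatnonzero(diam >= best - 1e-9)[0])
    _, radius = min_bounding_sphere(mesh.vertices)
    return SizeIndices(
        V=V, S=S, Dn=plane.neck_diameter, Dmax=float(diam[i_best]),
        H=H, aSz=2.0 * radius, H_Dmax=float(heights[i_best]),
    )


def hull_measures(
    mesh: TriSurfaceMesh, plane: OstiumPlane, aSz: float
) -> tuple[float, float]:
    """Convex-hull volume and neck-free hull surface area (V_CH, S_CH).

    Hull faces whose centroids lie within ``1e-6 * aSz`` of the neck plane
    are the flat closure of the ostium and are excluded from S_CH, mirroring
    the neck-free definition of the dome surface area S.
    """
    hull = convex_hull(mesh)
    v_ch = float(hull.to_trimesh().volume)
    centroids = hull.vertices[hull.faces].mean(axis=1)
    dist = np.abs(plane.signed_distance(centroids))
    keep = dist > 1e-6 * aSz
    s_ch = float(hull.face_areas[keep].sum())
    return v_ch, s_ch


def compute_shape_indices(
    mesh: TriSurfaceMesh, plane: OstiumPlane, size: SizeIndices
) -> ShapeIndices:
    if size.Dn <= 0:
        raise MeshError("neck diameter is zero")
    if size.H <= 0:
        raise MeshError("dome height is zero")
    v_ch, s_ch = hull_measures(mesh, plane, size.aSz)
    nsi = 1.0 - SPHERE_CONST * size.V ** (2.0 / 3.0) / size.S
    ei = 1.0 - SPHERE_CONST * v_ch ** (2.0 / 3.0) / s_ch
    ui = 1.0 - size.V / v_ch
    if ui < 0:
        # capped volume and hull agree to rounding for convex domes
        ui = 0.0 if ui > -1e-6 else ui
    return ShapeIndices(
        AR=size.H / size.Dn,
        BF=size.Dmax / size.Dn,
        CP=0.5 - size.H_Dmax / size.H,
        NSI=nsi,
        EI=ei,
        UI=ui,
    )


def geometry_indices(
    mesh: TriSurfaceMesh, plane: OstiumPlane, cut_type: str = "dome"
) -> dict[str, float]:
    """All 12 geometry indices as an ordered name -> value mapping."""
    size = compute_size_indices(mesh, plane, cut_type=cut_type)
    shape = compute_shape_indices(mesh, plane, size)
    return {
        "V": size.V, "S": size.S, "Dn": size.Dn, "Dmax": size.Dmax,
        "H": size.H, "aSz": size.aSz,
        "AR": shape.AR, "BF": shape.BF, "CP": shape.CP,
        "NSI": shape.NSI, "EI": shape.EI, "UI": shape.UI,
    }
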