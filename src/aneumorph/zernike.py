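"""Surface-based 3D Zernike moments, rotation invariants and energies.

The dome surface is mapped into the unit ball (centered on its area
centroid, scaled so the farthest vertex sits at radius 0.7) and rasterized
into a cubic occupancy grid.  Complex 3D Zernike moments are then obtained
by projecting the occupancy function onto the orthogonal Zernike basis

    Z_nl^m(r, theta, phi) = R_nl(r) * Y_l^m(theta, phi)

with the radial polynomials of the Canterakis normalization (the standard
q-coefficient form).  The rotation-invariant descriptor collapses the
magnetic index by the Euclidean norm per (n, l):

    F_nl = sqrt( sum_m |Omega_nl^m|^2 )

which for the default maximum order n = 20 yields 121 invariants (l <= n,
n - l even).  The normalized Zernike energy for a maximum order N is the
weighted sum of squared invariants with n <= N divided by the fill ratio,
i.e. the dome volume over the volume of its minimal bounding sphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.special import sph_harm_y

from .mesh import MeshError, TriSurfaceMesh

#: default rasterization grid (voxels per side) and unit-ball margin
DEFAULT_GRID = 64
SCALE_ANCHOR = 0.7
DEFAULT_ORDER = 20
#: maximum orders N for the normalized Zernike energies
DEFAULT_ENERGY_ORDERS = (2, 3, 6, 10, 20)


@dataclass(frozen=True)
class UnitBallVoxelization:
    occupied: np.ndarray       # (k, 3) voxel indices
    weights: np.ndarray        # (k,) surface-area measure per voxel, sums to 1
    grid: int
    offset: np.ndarray         # mm; subtracted before scaling
    scale: float               # mm^-1; multiplied after centering

    @property
    def centers(self) -> np.ndarray:
        """Voxel centers in unit-ball coordinates."""
        return (self.occupied + 0.5) / self.grid * 2.0 - 1.0

    @property
    def voxel_volume(self) -> float:
        return (2.0 / self.grid) ** 3


@dataclass(frozen=True)
class ZernikeInvariants:
    values: np.ndarray          # F_nl, ordered by (n, l)
    index: tuple[tuple[int, int], ...]

    def as_dict(self) -> dict[str, float]:
        return {f"ZMI_{n}_{l}": float(v) for (n, l), v in zip(self.index, self.values)}


@dataclass(frozen=True)
class ZernikeEnergies:
    energies: dict[int, float]  # N -> Z_N^surf
    fill_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {f"Zsurf_{n}": float(v) for n, v in self.energies.items()}


def invariant_index(n_max: int = DEFAULT_ORDER) -> tuple[tuple[int, int], ...]:
    """(n, l) pairs with 0 <= l <= n <= n_max and n - l even; 121 for n_max=20."""
    return tuple((n, l) for n in range(n_max + 1) for l in range(n % 2, n + 1, 2))


def voxelize_surface(mesh: TriSurfaceMesh, grid: int = DEFAULT_GRID) -> UnitBallVoxelization:
    """Rasterize the surface into a unit-ball occupancy grid.

    Occupancy is exact: a voxel is occupied iff some triangle intersects it
    (separating-axis triangle/box test).  Voxel weights carry the surface
    area deposited by a deterministic half-voxel-pitch barycentric sample
    grid per triangle, approximating the smooth surface measure (grazed
    voxels may carry zero weight).  The area weighting is what keeps the
    moment invariants stable under rotation at moderate grid sizes.
    """
    if grid < 16:
        raise MeshError("voxel grid must be at least 16")
    v = mesh.vertices
    fa = mesh.face_areas
    centroid = (v[mesh.faces].mean(axis=1) * fa[:, None]).sum(axis=0) / fa.sum()
    # round at the geometric merge tolerance so centering is exactly
    # translation invariant despite floating-point cancellation
    centered = np.round(v - centroid, 9)
    rmax = np.linalg.norm(centered, axis=1).max()
    scale = SCALE_ANCHOR / rmax
    pts = centered * scale  # all |pts| <= 0.7

    h = 2.0 / grid
    tri = pts[mesh.faces]  # (F, 3, 3)
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    longest = np.maximum(
        np.linalg.norm(e1, axis=1),
        np.maximum(np.linalg.norm(e2, axis=1), np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1)),
    )
    n_sub = np.maximum(1, np.ceil(longest / (0.5 * h)).astype(int))
    density = np.zeros(grid ** 3)
    for levels in np.unique(n_sub):
        faces = np.flatnonzero(n_sub == levels)
        ii, jj = np.meshgrid(np.arange(levels + 1), np.arange(levels + 1), indexing="ij")
        keep = (ii + jj) <= levels
        u = (ii[keep] / levels)[None, :, None]
        w = (jj[keep] / levels)[None, :, None]
        samples = tri[faces, 0][:, None, :] + u * e1[faces][:, None, :] + w * e2[faces][:, None, :]
        vox = np.floor((samples + 1.0) / h).astype(np.int64)
        np.clip(vox, 0, grid - 1, out=vox)
        flat = (vox[..., 0] * grid + vox[..., 1]) * grid + vox[..., 2]
        per_sample = (fa[faces] / flat.shape[1])[:, None]
        np.add.at(density, flat.ravel(), np.broadcast_to(per_sample, flat.shape).ravel())
    occupied_mask = density > 0
    # exact occupancy: mark every voxel a triangle actually intersects
    for t in tri:
        _mark_triangle_voxels(t, grid, h, occupied_mask)
    nz = np.flatnonzero(occupied_mask)
    if len(nz) == 0:
        raise MeshError("voxelization produced no occupied voxels")
    occ = np.column_stack([nz // grid ** 2, (nz // grid) % grid, nz % grid])
    weights = density[nz] / density.sum()
    return UnitBallVoxelization(
        occupied=occ, weights=weights, grid=grid, offset=centroid, scale=scale
    )


def _mark_triangle_voxels(t: np.ndarray, grid: int, h: float, mask: np.ndarray) -> None:
    """Set True for all voxels overlapping triangle ``t`` (separating axes)."""
    lo = np.clip(np.floor((t.min(axis=0) + 1.0) / h).astype(int), 0, grid - 1)
    hi = np.clip(np.floor((t.max(axis=0) + 1.0) / h).astype(int), 0, grid - 1)
    gx, gy, gz = np.meshgrid(
        *(np.arange(lo[k], hi[k] + 1) for k in range(3)), indexing="ij"
    )
    centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) * h + (h / 2 - 1.0)
    half = h / 2
    ok = np.ones(len(centers), dtype=bool)
    edges = (t[1] - t[0], t[2] - t[1], t[0] - t[2])
    axes = [np.cross(edges[0], edges[1])]
    for e in edges:
        for k in range(3):
            u = np.zeros(3)
            u[k] = 1.0
            a = np.cross(e, u)
            if np.abs(a).sum() > 1e-12:
                axes.append(a)
    for a in axes:
        p = (t @ a)[None, :] - (centers[ok] @ a)[:, None]
        r = half * np.abs(a).sum()
        sep = (p.min(axis=1) > r + 1e-12) | (p.max(axis=1) < -r - 1e-12)
        sub = np.flatnonzero(ok)
        ok[sub[sep]] = False
        if not ok.any():
            return
    idx = np.flatnonzero(ok)
    cells = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)[idx]
    flat = (cells[:, 0] * grid + cells[:, 1]) * grid + cells[:, 2]
    mask[flat] = True


def radial_coefficients(n: int, l: int) -> np.ndarray:
    """Coefficients q_klv of R_nl(r) = sum_v q_klv r^(2v+l)."""
    k = (n - l) // 2
    pref = (-1) ** k / 4.0 ** k * np.sqrt((2 * l + 4 * k + 3) / 3.0) * comb(2 * k, k)
    out = np.empty(k + 1)
    for nu in range(k + 1):
        out[nu] = (
            pref
            * (-1) ** nu
            * comb(k, nu)
            * comb(2 * (k + l + nu) + 1, 2 * k)
            / comb(k + l + nu, k)
        )
    return out


def zernike_invariants(
    vox: UnitBallVoxelization, n_max: int = DEFAULT_ORDER
) -> ZernikeInvariants:
    if n_max > 20:
        raise MeshError("orders above 20 are not supported by default")
    x = vox.centers
    r = np.linalg.norm(x, axis=1)
    r_safe = np.clip(r, 1e-12, None)
    theta = np.arccos(np.clip(x[:, 2] / r_safe, -1.0, 1.0))
    phi = np.arctan2(x[:, 1], x[:, 0])
    f = vox.weights

    # powers of r reused across all (n, l)
    r_pow = {p: r ** p for p in range(n_max + 1)}
    index = invariant_index(n_max)
    values = np.zeros(len(index))
    # cache Y_lm for m >= 0
    ylm_cache: dict[tuple[int, int], np.ndarray] = {}
    for pos, (n, l) in enumerate(index):
        coeffs = radial_coefficients(n, l)
        rad = np.zeros_like(r)
        for nu, q in enumerate(coeffs):
            rad += q * r_pow[2 * nu + l]
        total = 0.0
        for m in range(l + 1):
            key = (l, m)
            if key not in ylm_cache:
                ylm_cache[key] = sph_harm_y(l, m, theta, phi)
            omega = (3.0 / (4.0 * np.pi)) * np.sum(f * rad * np.conj(ylm_cache[key]))
            mag2 = abs(omega) ** 2
            total += mag2 if m == 0 else 2.0 * mag2  # |Omega_-m| = |Omega_m|
        values[pos] = np.sqrt(total)
    return ZernikeInvariants(values=values, index=index)


def zernike_energies(
    inv: ZernikeInvariants,
    volume: float,
    a_sz: float,
    orders=DEFAULT_ENERGY_ORDERS,
    weights: dict[tuple[int, int], float] | None = None,
) -> ZernikeEnergies:
    """Normalized Zernike energies Z_N^surf.

    Z_N = sum_{n <= N, l} w_nl F_nl^2 / fill, with fill the ratio of the
    dome volume to the volume of its minimal bounding sphere (diameter
    ``a_sz``).  Default weights are 1.
    """
    if volume <= 0 or a_sz <= 0:
        raise MeshError("volume and bounding-sphere diameter must be positive")
    fill = volume / ((4.0 / 3.0) * np.pi * (a_sz / 2.0) ** 3)
    if not 0.0 < fill <= 1.0 + 1e-9:
        raise MeshError(f"fill ratio {fill:.4f} outside (0, 1]")
    energies = {}
    for n_cut in orders:
        total = 0.0
        for (n, l), f in zip(inv.index, inv.values):
            if n <= n_cut:
                w = 1.0 if weights is None else weights.get((n, l), 1.0)
                total += w * f * f
        energies[int(n_cut)] = total / fill
    return ZernikeEnergies(energies=energies, fill_ratio=float(fill))
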