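"""Per-vertex surface writhe numbers and their aggregate indices.

The surface writhe at a vertex p collects Gauss-integral interactions
between the local surface orientation and every other surface patch: each
face c outside a small exclusion zone around p contributes

    g(p, c) = [(n_p x n_c) . (b_c - p) / |b_c - p|^3] * A_c

with b_c the face barycenter, n_c its unit normal and A_c its area.  The
L1 and L2 writhe numbers are the corresponding norms of the contribution
vector, scaled by 1/4pi:

    W_Lk(p) = (1/4pi) * (sum_c |g(p, c)|^k)^(1/k)

A perfectly symmetric neighbourhood cancels in the signed sense, so large
writhe flags asymmetry and "twisting" of the surrounding surface.  The
area-normalized variants divide by the total surface area S, removing the
size dependence.  Eight aggregate indices are formed: area-weighted mean
and histogram entropy for each of {L1, L2} x {raw, normalized}.

The exclusion zone is the union of p's one-ring (where the kernel
diverges) and a metric ball of radius ``EXCLUSION_FRACTION * sqrt(S)``.
The metric component keeps the excluded neighbourhood independent of mesh
resolution — with a purely combinatorial exclusion the indices drift with
refinement because the near-field cutoff shrinks with edge length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curvature import weighted_entropy
from .mesh import MeshError, TriSurfaceMesh

#: vertices above this count are subsampled (uniform-area, seeded) before
#: the O(V*F) evaluation; an approximation knob, not a model parameter
MAX_EVAL_POINTS = 5000

#: near-field exclusion radius as a fraction of sqrt(total surface area)
EXCLUSION_FRACTION = 0.05


@dataclass(frozen=True)
class WritheField:
    w_l1: np.ndarray       # W_L1 per evaluated vertex (dimensionless)
    w_l2: np.ndarray       # W_L2
    wn_l1: np.ndarray      # W_L1 / S (mm^-2)
    wn_l2: np.ndarray      # W_L2 / S
    areas: np.ndarray      # vertex area weights of the evaluated vertices
    vertex_indices: np.ndarray


@dataclass(frozen=True)
class WritheIndices:
    W_mean_L1: float
    W_mean_L2: float
    W_H_L1: float
    W_H_L2: float
    Wn_mean_L1: float
    Wn_mean_L2: float
    Wn_H_L1: float
    Wn_H_L2: float


def writhe_field(
    mesh: TriSurfaceMesh,
    max_points: int = MAX_EVAL_POINTS,
    seed: int = 0,
    chunk: int = 128,
) -> WritheField:
    if mesh.n_faces < 100:
        raise MeshError("writhe needs a mesh with at least 100 faces")
    v = mesh.vertices
    vn = mesh.vertex_normals
    fn = mesh.face_normals
    fa = mesh.face_areas
    bc = v[mesh.faces].mean(axis=1)
    va = mesh.vertex_areas
    s_total = float(fa.sum())

    idx = np.arange(mesh.n_vertices)
    if mesh.n_vertices > max_points:
        rng = np.random.default_rng(seed)
        p = va / va.sum()
        idx = np.sort(rng.choice(mesh.n_vertices, size=max_points, replace=False, p=p))

    # one-ring faces per vertex, as a boolean lookup built from face indices
    ring = [[] for _ in range(mesh.n_vertices)]
    for fi, face in enumerate(mesh.faces):
        for vi in face:
            ring[vi].append(fi)

    r_excl = EXCLUSION_FRACTION * np.sqrt(s_total)
    w1 = np.empty(len(idx))
    w2 = np.empty(len(idx))
    for start in range(0, len(idx), chunk):
        sel = idx[start:start + chunk]
        p = v[sel]                       # (B, 3)
        n_p = vn[sel]
        d = bc[None, :, :] - p[:, None, :]           # (B, F, 3)
        dist = np.linalg.norm(d, axis=2)
        cross = np.cross(np.broadcast_to(n_p[:, None, :], d.shape), fn[None, :, :])
        g = np.einsum("bfk,bfk->bf", cross, d) / np.clip(dist, 1e-300, None) ** 3 * fa
        g[dist < r_excl] = 0.0
        for bi, vi in enumerate(sel):
            g[bi, ring[vi]] = 0.0
        w1[start:start + chunk] = np.abs(g).sum(axis=1) / (4.0 * np.pi)
        w2[start:start + chunk] = np.sqrt((g ** 2).sum(axis=1)) / (4.0 * np.pi)

    if not np.all(np.isfinite(w1)):
        raise MeshError("writhe evaluation produced non-finite values")
    return WritheField(
        w_l1=w1, w_l2=w2, wn_l1=w1 / s_total, wn_l2=w2 / s_total,
        areas=va[idx], vertex_indices=idx,
    )


def writhe_indices(field: WritheField) -> WritheIndices:
    a = field.areas
    wsum = a.sum()

    def mean(x):
        return float(np.sum(x * a) / wsum)

    return WritheIndices(
        W_mean_L1=mean(field.w_l1),
        W_mean_L2=mean(field.w_l2),
        W_H_L1=weighted_entropy(field.w_l1, a),
        W_H_L2=weighted_entropy(field.w_l2, a),
        Wn_mean_L1=mean(field.wn_l1),
        Wn_mean_L2=mean(field.wn_l2),
        Wn_H_L1=weighted_entropy(field.wn_l1, a),
        Wn_H_L2=weighted_entropy(field.wn_l2, a),
    )
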