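"""Assembly of the canonical per-case shape descriptor.

A descriptor is an ordered, named vector of morphometric features for one
case and cut type.  Canonical column order: the 12 geometry indices (only
for dome-type cuts), 8 curvature indices, 8 writhe indices, 121 Zernike
invariants and the normalized Zernike energies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import curvature as _curv
from . import geometry as _geom
from . import writhe as _wr
from . import zernike as _z
from .mesh import TriSurfaceMesh, extract_neck, fit_neck_plane

GEOMETRY_FEATURES = ("V", "S", "Dn", "Dmax", "H", "aSz",
                     "AR", "BF", "CP", "NSI", "EI", "UI")
SIZE_FEATURES = GEOMETRY_FEATURES[:6]
SHAPE_FEATURES = GEOMETRY_FEATURES[6:]
CURVATURE_FEATURES = ("GLN", "MLN", "NGLN", "NMLN", "GLN_CH", "MLN_CH", "GH", "MH")
WRITHE_FEATURES = ("W_mean_L1", "W_mean_L2", "W_H_L1", "W_H_L2",
                   "Wn_mean_L1", "Wn_mean_L2", "Wn_H_L1", "Wn_H_L2")
ZMI_FEATURES = tuple(f"ZMI_{n}_{l}" for n, l in _z.invariant_index())
ENERGY_FEATURES = tuple(f"Zsurf_{n}" for n in _z.DEFAULT_ENERGY_ORDERS)

ALL_FEATURES = (GEOMETRY_FEATURES + CURVATURE_FEATURES + WRITHE_FEATURES
                + ZMI_FEATURES + ENERGY_FEATURES)

FAMILIES = {
    "geometry": GEOMETRY_FEATURES,
    "curvature": CURVATURE_FEATURES,
    "writhe": WRITHE_FEATURES,
    "zernike": ZMI_FEATURES + ENERGY_FEATURES,
}

#: feature-category map used by the cut-comparison summary
CATEGORIES = {
    **{f: "GI size" for f in SIZE_FEATURES},
    **{f: "GI shape" for f in SHAPE_FEATURES},
    **{f: "curvature" for f in CURVATURE_FEATURES},
    **{f: "writhe" for f in WRITHE_FEATURES},
    **{f: "ZMI" for f in ZMI_FEATURES},
    **{f: "ZMI energy" for f in ENERGY_FEATURES},
}


def compute_descriptor(
    mesh: TriSurfaceMesh,
    cut_type: str = "dome",
    families=("geometry", "curvature", "writhe", "zernike"),
    zernike_grid: int = _z.DEFAULT_GRID,
    writhe_max_points: int = _wr.MAX_EVAL_POINTS,
    seed: int = 0,
) -> dict[str, float]:
    """Compute the requested feature families for one cut mesh.

    Geometry indices require a dome-type cut (*dome*/*ninja*).  The Zernike
    energies also need the dome volume and bounding-sphere diameter, so the
    'zernike' family computes the neck plane even when 'geometry' is not
    requested.
    """
    out: dict[str, float] = {}
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")

    plane = None
    if cut_type in ("dome", "ninja") and ("geometry" in families or "zernike" in families):
        plane = fit_neck_plane(extract_neck(mesh), mesh)

    gi = None
    if "geometry" in families:
        gi = _geom.geometry_indices(mesh, plane, cut_type=cut_type)
        out.update(gi)
    if "curvature" in families:
        field = _curv.estimate_curvature(mesh)
        ci = _curv.curvature_indices(field, mesh)
        out.update(vars(ci))
    if "writhe" in families:
        wf = _wr.writhe_field(mesh, max_points=writhe_max_points, seed=seed)
        out.update(vars(_wr.writhe_indices(wf)))
    if "zernike" in families:
        vox = _z.voxelize_surface(mesh, grid=zernike_grid)
        inv = _z.zernike_invariants(vox)
        out.update(inv.as_dict())
        if plane is not None:
            if gi is not None:
                vol, a_sz = gi["V"], gi["aSz"]
            else:
                from .mesh import enclosed_volume, min_bounding_sphere
                vol = enclosed_volume(mesh, plane)
                a_sz = 2.0 * min_bounding_sphere(mesh.vertices)[1]
            out.update(_z.zernike_energies(inv, vol, a_sz).as_dict())
    return out


def feature_frame(records, features=None) -> pd.DataFrame:
    """Stack record descriptors into a canonical-order DataFrame."""
    rows, index = [], []
    for rec in records:
        if rec.descriptor is None:
            raise ValueError(f"record {rec.case_id} has no descriptor")
        rows.append(rec.descriptor)
        index.append(rec.case_id)
    df = pd.DataFrame(rows, index=index)
    order = [f for f in (features or ALL_FEATURES) if f in df.columns]
    df = df[order]
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing feature values in columns {bad}")
    return df.astype(np.float64)
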