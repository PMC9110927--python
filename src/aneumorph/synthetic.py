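"""Parametric synthetic aneurysm domes and labeled cohorts.

Real dome meshes are segmented from 3D rotational angiograms and cut free
from the parent vasculature; none are shipped here.  This module generates
stand-in geometry with controllable size, elongation and undulation
(blebs/lobules), plus cohorts whose rupture label follows a logistic model
in shape irregularity, size and anatomical location — the statistical
structure needed to exercise the morphometric benchmark end-to-end.

All randomness uses ``numpy.random.default_rng`` (PCG64) seeded explicitly,
so identical specs yield bit-identical meshes on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.special import sph_harm_y

from .mesh import MeshError, TriSurfaceMesh

#: the 12 anatomical location categories used throughout
LOCATIONS = (
    "MCA bif", "PComA", "AComA", "ICA oph", "ICA bif", "MCA",
    "BA tip", "ICA cav", "ACA", "VB other", "ICA chor", "PCA",
)

#: unruptured/ruptured case counts per location (clinical cohort totals)
LOCATION_COUNTS = {
    "MCA bif": (109, 42),
    "PComA": (54, 76),
    "AComA": (47, 72),
    "ICA oph": (103, 11),
    "ICA bif": (28, 10),
    "MCA": (35, 2),
    "BA tip": (20, 17),
    "ICA cav": (34, 0),
    "ACA": (15, 12),
    "VB other": (14, 9),
    "ICA chor": (13, 7),
    "PCA": (2, 3),
}


def location_priors(smoothing: float = 0.5) -> dict[str, float]:
    """Per-location rupture probabilities from the cohort totals.

    A Laplace-style ``smoothing`` pseudo-count keeps the logit finite for
    locations with zero observed ruptures (ICA cav).
    """
    return {
        loc: (r + smoothing) / (u + r + 2 * smoothing)
        for loc, (u, r) in LOCATION_COUNTS.items()
    }


@dataclass(frozen=True)
class Bleb:
    """A smooth Gaussian outward bump on the dome surface."""

    direction: tuple[float, float, float]  # unit direction from dome center
    radius: float  # angular footprint expressed as mm at the dome surface
    height: float  # radial amplitude, mm


@dataclass(frozen=True)
class DomeSpec:
    """Specification of a single synthetic cut dome.

    ``radii`` are the half-axes (a, b, c) of the base half-ellipsoid in mm;
    c is the height axis.  ``undulation_amplitude`` is a fraction of the
    local radius modulated by a real spherical harmonic of
    ``undulation_degree``.  ``resolution`` is the number of latitude rings
    (faces grow quadratically with it).  ``cut_type`` 'dome' gives a planar
    neck; 'ninja' perturbs the neck line sinusoidally by
    ``ninja_amplitude`` mm.
    """

    radii: tuple[float, float, float] = (1.0, 1.0, 1.0)
    blebs: tuple[Bleb, ...] = ()
    undulation_amplitude: float = 0.0
    undulation_degree: int = 5
    resolution: int = 24
    cut_type: str = "dome"
    ninja_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.radii) <= 0:
            raise MeshError("radii must be positive")
        if not 0.0 <= self.undulation_amplitude <= 0.5:
            raise MeshError("undulation amplitude must lie in [0, 0.5]")
        if self.cut_type not in ("dome", "ninja"):
            raise MeshError("cut_type must be 'dome' or 'ninja'")
        for b in self.blebs:
            if b.height >= min(self.radii):
                raise MeshError("bleb larger than dome: self-intersecting spec")


def make_dome(spec: DomeSpec) -> TriSurfaceMesh:
    """Generate an open dome mesh from a :class:`DomeSpec`.

    The surface is a radial graph over the upper half-sphere: a point at
    spherical angles (theta, phi) sits at ``rho(theta, phi)`` times the base
    half-ellipsoid position.  Blebs and undulation multiply the radial
    factor and vanish nowhere; the *dome* cut boundary lies exactly in the
    z = 0 plane because z = rho * c * cos(theta) is zero at the equator.
    """
    rng = np.random.default_rng(spec.seed)
    a, b, c = spec.radii
    n_t = spec.resolution
    n_p = 2 * spec.resolution

    phi = np.linspace(0.0, 2.0 * np.pi, n_p, endpoint=False)
    if spec.cut_type == "ninja" and spec.ninja_amplitude != 0.0:
        # non-planar neck: the polar extent of each meridian is modulated
        theta_max = np.pi / 2 - (spec.ninja_amplitude / c) * np.sin(3.0 * phi)
    else:
        theta_max = np.full(n_p, np.pi / 2)

    # rings i = 1..n_t (i=0 is the pole vertex)
    frac = np.arange(1, n_t + 1) / n_t
    theta = frac[:, None] * theta_max[None, :]  # (n_t, n_p)
    pp = np.broadcast_to(phi[None, :], theta.shape)

    rho = np.ones_like(theta)
    if spec.undulation_amplitude > 0:
        rho = rho + spec.undulation_amplitude * _undulation(
            theta, pp, spec.undulation_degree, rng
        )
    mean_r = (a * b * c) ** (1.0 / 3.0)
    for bleb in spec.blebs:
        d = np.asarray(bleb.direction, dtype=float)
        d = d / np.linalg.norm(d)
        ux = np.sin(theta) * np.cos(pp)
        uy = np.sin(theta) * np.sin(pp)
        uz = np.cos(theta)
        ang = np.arccos(np.clip(ux * d[0] + uy * d[1] + uz * d[2], -1.0, 1.0))
        sigma = bleb.radius / mean_r
        rho = rho + (bleb.height / mean_r) * np.exp(-0.5 * (ang / sigma) ** 2)

    ring_pts = np.stack(
        [
            rho * a * np.sin(theta) * np.cos(pp),
            rho * b * np.sin(theta) * np.sin(pp),
            rho * c * np.cos(theta),
        ],
        axis=-1,
    ).reshape(-1, 3)
    pole = np.array([[0.0, 0.0, float(rho[0].mean() * c)]])
    # pole height: use the unperturbed pole of the radial graph
    pole_rho = 1.0
    if spec.undulation_amplitude > 0:
        pole_rho += spec.undulation_amplitude * float(
            _undulation(np.zeros((1, 1)), np.zeros((1, 1)), spec.undulation_degree,
                        np.random.default_rng(spec.seed))[0, 0]
        )
    for bleb in spec.blebs:
        d = np.asarray(bleb.direction, dtype=float)
        d = d / np.linalg.norm(d)
        ang = np.arccos(np.clip(d[2], -1.0, 1.0))
        sigma = bleb.radius / mean_r
        pole_rho += (bleb.height / mean_r) * np.exp(-0.5 * (ang / sigma) ** 2)
    pole = np.array([[0.0, 0.0, pole_rho * c]])

    vertices = np.vstack([pole, ring_pts])

    def vid(i, j):  # ring i (1-based), meridian j
        return 1 + (i - 1) * n_p + (j % n_p)

    faces = []
    for j in range(n_p):
        faces.append([0, vid(1, j), vid(1, j + 1)])
    for i in range(1, n_t):
        for j in range(n_p):
            v00, v01 = vid(i, j), vid(i, j + 1)
            v10, v11 = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    return TriSurfaceMesh(vertices, np.asarray(faces))


def _undulation(theta, phi, degree, rng) -> np.ndarray:
    """Random real spherical-harmonic bump pattern, normalized to [-1, 1]."""
    coeffs = rng.standard_normal(degree + 1)
    out = np.zeros_like(theta, dtype=float)
    for m in range(degree + 1):
        y = sph_harm_y(degree, m, theta, phi)
        out += coeffs[m] * (y.real if m == 0 else np.sqrt(2.0) * y.real)
    scale = np.abs(out).max()
    return out / scale if scale > 0 else out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generative specification for a labeled synthetic cohort.

    Rupture labels are drawn from a logistic model
    ``logit p = beta0(location) + beta_shape * z_irr + beta_size * z_size + eps``
    where z_irr and z_size are standard-normal per-case latent variables and
    eps is Gaussian noise of scale ``noise_scale``.  The per-location
    intercepts default to the logits of the clinical rupture fractions;
    shape irregularity dominates size by default, matching the qualitative
    finding that irregularity carries most of the discriminative signal.
    """

    n_cases: int = 200
    beta_shape: float = 1.5
    beta_size: float = 0.3
    noise_scale: float = 0.5
    location_effects: bool = True
    seed: int = 0
    resolution: int = 16
    cut_type: str = "dome"
    dataset: str = "synthetic"


@dataclass
class AneurysmRecord:
    """One case: identity, labels and (optionally) its shape descriptor."""

    case_id: str
    dataset: str
    cut_type: str
    location: str
    ruptured: bool
    descriptor: dict | None = None
    params: dict = dfield(default_factory=dict)


def _case_spec(u, scale, resolution, cut_type, seed) -> DomeSpec:
    """Map the irregularity fraction u and size scale (mm) to a dome spec.

    The mapping is monotone in both knobs: irregularity raises elongation,
    undulation and bleb amplitude together (so NSI/UI/writhe respond to it),
    while size is a pure isotropic scale (so V/S/aSz respond to it).
    """
    elong = 1.0 + 0.9 * u
    rng = np.random.default_rng(seed)
    d = rng.standard_normal(3)
    d[2] = abs(d[2]) + 0.5
    d /= np.linalg.norm(d)
    blebs = ()
    if u > 0.15:
        blebs = (Bleb(direction=tuple(d), radius=0.45 * scale, height=0.45 * u * scale),)
    return DomeSpec(
        radii=(scale, scale, elong * scale),
        blebs=blebs,
        undulation_amplitude=0.22 * u,
        undulation_degree=6,
        resolution=resolution,
        cut_type=cut_type,
        ninja_amplitude=0.15 * scale if cut_type == "ninja" else 0.0,
        seed=seed,
    )


def make_cohort(
    spec: CohortSpec, generate_meshes: bool = True
) -> list[tuple[TriSurfaceMesh | None, AneurysmRecord]]:
    """Draw a labeled cohort of synthetic domes.

    Returns (mesh, record) pairs; the generative latents and logistic score
    of every case are logged in ``record.params`` so that oracle
    discriminative performance can be computed independently of any
    measured feature.
    """
    if spec.n_cases <= 0:
        raise MeshError("empty cohort")
    rng = np.random.default_rng(spec.seed)
    priors = location_priors()
    locs = list(LOCATIONS)
    totals = np.array([sum(LOCATION_COUNTS[l]) for l in locs], dtype=float)
    p_loc = totals / totals.sum()

    out = []
    for i in range(spec.n_cases):
        loc = locs[rng.choice(len(locs), p=p_loc)]
        z_irr = float(rng.standard_normal())
        z_size = float(rng.standard_normal())
        eps = float(rng.standard_normal()) * spec.noise_scale
        beta0 = float(np.log(priors[loc] / (1 - priors[loc]))) if spec.location_effects else 0.0
        score = beta0 + spec.beta_shape * z_irr + spec.beta_size * z_size
        p = 1.0 / (1.0 + np.exp(-(score + eps)))
        ruptured = bool(rng.random() < p)
        case_seed = int(rng.integers(0, 2**31 - 1))
        from scipy.stats import norm

        u = float(norm.cdf(z_irr))          # irregularity fraction in (0, 1)
        scale = 2.8 * float(np.exp(0.45 * z_size))  # size scale, mm
        mesh = None
        if generate_meshes:
            mesh = make_dome(
                _case_spec(u, scale, spec.resolution, spec.cut_type, case_seed)
            )
        rec = AneurysmRecord(
            case_id=f"{spec.dataset}-{i:04d}",
            dataset=spec.dataset,
            cut_type=spec.cut_type,
            location=loc,
            ruptured=ruptured,
            params={
                "z_irr": z_irr,
                "z_size": z_size,
                "u_irr": u,
                "scale": scale,
                "score": float(score),
                "p_rupture": float(p),
                "case_seed": case_seed,
            },
        )
        out.append((mesh, rec))
    return out


def oracle_auc(records: list[AneurysmRecord], param: str = "score") -> float:
    """Empirical AUC of a logged generative quantity against the drawn labels.

    This is the reference discriminative performance a feature can attain if
    it is a monotone readout of that generative quantity.
    """
    y = np.array([r.ruptured for r in records], dtype=bool)
    s = np.array([r.params[param] for r in records], dtype=float)
    if y.all() or not y.any():
        raise MeshError("oracle AUC needs both classes")
    from scipy.stats import rankdata

    ranks = rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
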