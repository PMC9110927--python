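import numpy as np
import pytest
import trimesh

from aneumorph import (
    DomeSpec,
    Bleb,
    TriSurfaceMesh,
    extract_neck,
    fit_neck_plane,
    make_dome,
)


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    a, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(a) < 0:
        a[:, 0] = -a[:, 0]
    return a


@pytest.fixture(scope="session")
def icosphere():
    """Closed unit sphere, 5120 faces."""
    return TriSurfaceMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=4))


@pytest.fixture(scope="session")
def hemisphere():
    """Open unit hemisphere dome with a planar neck."""
    return make_dome(DomeSpec(resolution=48))


@pytest.fixture(scope="session")
def hemisphere_plane(hemisphere):
    return fit_neck_plane(extract_neck(hemisphere), hemisphere)


@pytest.fixture(scope="session")
def bleb_dome():
    """Unit dome with two outward blebs and mild undulation."""
    return make_dome(
        DomeSpec(
            resolution=32,
            blebs=(
                Bleb(direction=(0.6, 0.1, 0.8), radius=0.3, height=0.35),
                Bleb(direction=(-0.4, 0.5, 0.75), radius=0.25, height=0.3),
            ),
            undulation_amplitude=0.12,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def coarse_dome():
    """Small dome for brute-force (O(V*F)) oracles."""
    return make_dome(DomeSpec(resolution=10, seed=4))
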