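import numpy as np
import pytest

from toothseg.mesh import TriangleMesh
from toothseg.synthetic import JawSpec, generate_jaw


@pytest.fixture(scope="session")
def default_case():
    """Full 16-tooth synthetic arch in canonical pose."""
    return generate_jaw(JawSpec())


@pytest.fixture(scope="session")
def coarse_case():
    """Coarser arch (fewer faces) for heavier pipeline tests."""
    return generate_jaw(JawSpec(target_edge=1.4, seed=7))


@pytest.fixture
def two_triangle_mesh():
    """Two triangles sharing an edge in the z=0 plane."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0]]
    )
    faces = np.array([[0, 1, 2], [1, 3, 2]])
    return TriangleMesh(verts, faces)


@pytest.fixture
def unit_cube_mesh():
    """Closed unit cube, 12 triangles, total area 6."""
    v = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # front
            [2, 3, 7], [2, 7, 6],  # back
            [1, 2, 6], [1, 6, 5],  # right
            [3, 0, 4], [3, 4, 7],  # left
        ]
    )
    return TriangleMesh(v, f)


def make_sphere_mesh(radius=5.0, subdivisions=3):
    import trimesh

    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))
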