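import numpy as np
import pytest

from surfmorph import TriangleMesh, make_icosphere


def make_grid_mesh(n: int, spacing: float = 1.0, z: float = 0.0) -> TriangleMesh:
    """Regular planar triangulated grid, n x n vertices, +z face normals."""
    xs, ys = np.meshgrid(np.arange(n, dtype=float) * spacing,
                         np.arange(n, dtype=float) * spacing)
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b, c, d = a + 1, a + n, a + n + 1
            faces += [[a, b, d], [a, d, c]]
    return TriangleMesh(verts, np.asarray(faces))


def make_tetrahedron() -> TriangleMesh:
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(verts, faces)


@pytest.fixture(scope="session")
def grid41():
    return make_grid_mesh(41)


@pytest.fixture(scope="session")
def grid61():
    return make_grid_mesh(61)


@pytest.fixture(scope="session")
def ico3():
    return make_icosphere(3, 50.0)


@pytest.fixture(scope="session")
def ico4():
    return make_icosphere(4, 50.0)
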