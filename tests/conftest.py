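import sys
from pathlib import Path

import numpy as np
import pytest
import trimesh

sys.path.insert(0, str(Path(__file__).parent))

from tash.synthetic import SyntheticSpec, _grid_faces, generate_subject
from tash.types import TriangleSurface, VertexScalarField
from tash import mesh


def grid_surface(n: int = 12, spacing: float = 1.0,
                 height=None) -> TriangleSurface:
    xs = np.arange(n) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    z = np.zeros(n * n) if height is None else np.asarray(height).ravel()
    coords = np.column_stack([X.ravel(), Y.ravel(), z])
    return TriangleSurface(coords=coords, faces=_grid_faces(n, n))


@pytest.fixture(scope="session")
def grid12():
    return grid_surface(12)


@pytest.fixture(scope="session")
def grid12_graph(grid12):
    return mesh.build_adjacency(grid12)


@pytest.fixture(scope="session")
def grid30():
    return grid_surface(30)


@pytest.fixture(scope="session")
def grid30_graph(grid30):
    return mesh.build_adjacency(grid30)


@pytest.fixture(scope="session")
def icosphere10():
    ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return TriangleSurface(coords=np.asarray(ico.vertices, dtype=float),
                           faces=np.asarray(ico.faces),
                           surface_kind="synthetic")


@pytest.fixture(scope="session")
def tetrahedron():
    return TriangleSurface(
        coords=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        faces=np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]]),
    )


@pytest.fixture(scope="session")
def single_subject():
    return generate_subject(SyntheticSpec(morphotype="single", seed=11))


@pytest.fixture(scope="session")
def csd_subject():
    return generate_subject(SyntheticSpec(morphotype="csd", seed=12))


@pytest.fixture(scope="session")
def fpd_subject():
    return generate_subject(SyntheticSpec(morphotype="fpd", seed=13))


@pytest.fixture(scope="session")
def flat_slab():
    """White plane + pial plane offset 2.5 mm, uniform 2.5 mm thickness."""
    n, spacing = 30, 0.8
    white = grid_surface(n, spacing)
    pial = TriangleSurface(coords=white.coords + [0, 0, 2.5],
                           faces=white.faces, surface_kind="pial")
    thickness = VertexScalarField(values=np.full(n * n, 2.5), kind="thickness")
    return white, pial, thickness
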