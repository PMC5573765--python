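import numpy as np
import pytest

from avflow.synthetic import GeneratorConfig, gen_cylinder_mesh
from avflow.wall_analysis import SurfaceMesh


@pytest.fixture(scope="session")
def small_mesh() -> SurfaceMesh:
    """Coarse tube mesh shared by wall-analysis tests."""
    cfg = GeneratorConfig(seed=0, n_axial=10, n_circ=12)
    return gen_cylinder_mesh(cfg)


@pytest.fixture()
def two_face_mesh() -> SurfaceMesh:
    """Two equal-area triangles in one 'artery' ring."""
    vertices = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    region = np.array(["artery", "artery"], dtype=object)
    return SurfaceMesh(
        vertices=vertices, faces=faces, region=region,
        rings={"band": np.array([0, 1])},
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
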