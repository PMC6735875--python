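import numpy as np
import pytest

from scarconcord import PhantomConfig, SurfaceMesh, make_lv_phantom


def small_config(**overrides) -> PhantomConfig:
    """A down-scaled phantom that keeps the full geometry but runs fast."""
    defaults = dict(
        grid_shape=(40, 40, 40),
        spacing_mm=(1.6, 1.6, 1.6),
        lv_center_mm=(32.0, 32.0, 40.0),
        endo_radius_mm=(12.0, 12.0, 18.0),
        wall_thickness_mm=5.0,
        mesh_n_theta=48,
        mesh_n_phi=24,
        n_egm=150,
        n_pace=40,
        seed=7,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    cfg = small_config()
    image, wall, mesh, truth = make_lv_phantom(cfg)
    return cfg, image, wall, mesh, truth


@pytest.fixture()
def tetra_mesh() -> SurfaceMesh:
    """Surface of a tetrahedron: the smallest closed connected mesh."""
    v = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]])
    f = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return SurfaceMesh(v, f)


class PathMesh:
    """Duck-typed stand-in whose vertex graph is a simple path 0-1-...-n-1.

    Lets interpolation be checked against the closed-form solution of the
    discrete Laplace equation on a path, which a triangulated surface
    cannot realise.
    """

    def __init__(self, n: int):
        self.n_vertices = n

    def adjacency(self):
        from scipy.sparse import coo_matrix
        n = self.n_vertices
        i = np.concatenate([np.arange(n - 1), np.arange(1, n)])
        j = np.concatenate([np.arange(1, n), np.arange(n - 1)])
        return coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
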