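import numpy as np
import pytest
import trimesh

from pelvimetry3d.meshes import SurfaceMesh, VoxelSegmentation
from pelvimetry3d.phantoms import PhantomParams, make_template_pelvis


@pytest.fixture(scope="session")
def template():
    """Default phantom pelvis and its ground-truth landmarks."""
    return make_template_pelvis(PhantomParams())


@pytest.fixture(scope="session")
def template_model(template):
    return template[0]


@pytest.fixture(scope="session")
def template_truth(template):
    return template[1]


@pytest.fixture(scope="session")
def sphere_mesh():
    """Icosphere of radius 10 mm."""
    s = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    return SurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces), "ball")


@pytest.fixture()
def ball_segmentation():
    """Binary ball mask, radius 10 voxels, 1 mm isotropic spacing."""
    n = 24
    g = np.indices((n, n, n)).astype(float) - (n - 1) / 2
    mask = (g**2).sum(axis=0) <= 10.0**2
    return VoxelSegmentation(mask.astype(np.int32), np.eye(4), {"ball": 1})


def random_rigid(rng):
    """A uniformly random proper rotation + translation as a 4x4 matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = rng.uniform(-50, 50, 3)
    return m
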