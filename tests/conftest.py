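import numpy as np
import pytest

from dfsp.config import preset
from dfsp.io import PointCloud
from dfsp.pipeline import segment_cloud
from dfsp.synth import PlantSpec, generate_plant_with_truth


@pytest.fixture(scope="session")
def plant6():
    """A default 6-leaf synthetic plant with its ground truth."""
    return generate_plant_with_truth(PlantSpec(n_leaves=6, seed=1))


@pytest.fixture(scope="session")
def plant6_output(plant6):
    """Full-pipeline output for the 6-leaf plant at the 4096-point preset."""
    cloud, _ = plant6
    return segment_cloud(cloud, preset("points4096"))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_cloud():
    """Unit-cube corner cloud, handy for voxel/knn toys."""
    pts = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                   dtype=float)
    return PointCloud(pts)
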