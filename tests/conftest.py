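import numpy as np
import pytest

from ffnet3d.io import DatasetBundle, LabeledPointCloud
from ffnet3d.synthetic import PlantRecipe, generate_plant


@pytest.fixture(scope="session")
def small_plant() -> LabeledPointCloud:
    """A 4000-point labeled synthetic plant shared across tests."""
    return generate_plant(PlantRecipe(n_points_target=4000, seed=11))


@pytest.fixture()
def two_plant_bundle() -> DatasetBundle:
    clouds = []
    split = {}
    for s in (1, 2):
        c = generate_plant(PlantRecipe(n_points_target=1500, seed=s))
        c.plant_id = f"plant{s}"
        split[f"plant{s}"] = "train"
        clouds.append(c)
    return DatasetBundle(clouds=clouds, split=split)


def random_occupancy(rng: np.random.Generator, dim: int = 6,
                     p: float = 0.3) -> np.ndarray:
    """Random active-voxel coordinates on a dim³ grid (at least one site)."""
    occ = rng.random((dim, dim, dim)) < p
    if not occ.any():
        occ[tuple(rng.integers(0, dim, 3))] = True
    return np.argwhere(occ)
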