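import numpy as np
import pandas as pd
import pytest

from coproscope.hosts import HostMeta
from coproscope.trees import CalibratedTree


@pytest.fixture
def four_leaf_tree():
    """Ultrametric 4-leaf tree: root age 3, internal node ages 1 and 2."""
    return CalibratedTree.from_newick("((A:1,B:1):2,(C:2,D:2):1);")


@pytest.fixture
def study_meta():
    """The study's host design: 4 wolves, 5 dogs, 1 ancient sample."""
    return ([HostMeta(f"wolf{i + 1}", "wolf") for i in range(4)]
            + [HostMeta(f"dog{i + 1}", "dog") for i in range(5)]
            + [HostMeta("ancient1", "ancient")])


def make_two_block_community(seed=0, n_noise=28, uniform_dog_diet=True):
    """Perfectly separable 9-host community: 6 dog-only taxa, 6 wolf-only
    taxa, plus random noise taxa; diets two-valued when uniform."""
    rng = np.random.default_rng(seed)
    carb = 0.25 if uniform_dog_diet else None
    meta = [HostMeta(f"wolf{i + 1}", "wolf",
                     {"vertebrate_prey": 1.0, "carbohydrate_fibre": 0.0})
            for i in range(4)]
    meta += [HostMeta(f"dog{i + 1}", "dog",
                      {"vertebrate_prey": 1 - (carb if carb is not None
                                               else 0.1 + 0.075 * i),
                       "carbohydrate_fibre": (carb if carb is not None
                                              else 0.1 + 0.075 * i)})
             for i in range(5)]
    hosts = [m.host_id for m in meta]
    is_dog = np.array([m.group == "dog" for m in meta])
    cols = {f"dogtax{j}": is_dog.astype(int) for j in range(6)}
    cols |= {f"wolftax{j}": (~is_dog).astype(int) for j in range(6)}
    cols |= {f"noise{j}": rng.integers(0, 2, len(hosts))
             for j in range(n_noise)}
    return pd.DataFrame(cols, index=hosts), meta


@pytest.fixture
def two_block_community():
    return make_two_block_community()


def random_distance_matrix(rng, n=10):
    x = rng.random((n, n))
    x = (x + x.T) / 2
    np.fill_diagonal(x, 0.0)
    return x
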