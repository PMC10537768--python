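import numpy as np
import pytest
from hypothesis import settings

import pigback as pb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_scene():
    """One default-parameter labeled scene, seed 1."""
    return pb.generate_pig_scene(pb.SceneParams(seed=1))


@pytest.fixture(scope="session")
def filtered_scene(default_scene):
    cloud, truth = default_scene
    kept, removed, stats = pb.statistical_filter(cloud)
    return kept, removed, stats


@pytest.fixture(scope="session")
def pig_cluster(filtered_scene):
    kept, _, _ = filtered_scene
    labeling = pb.dbscan(kept)
    return pb.select_pig_cluster(kept, labeling)


@pytest.fixture(scope="session")
def aligned_pig(pig_cluster):
    aligned, angle = pb.align_horizontal(pig_cluster)
    return aligned


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cloud(rng, n, kind="mixture"):
    """Random test clouds: blob mixtures with sprinkled outliers."""
    if kind == "uniform":
        return pb.PointCloud(rng.uniform(-1, 1, (n, 3)))
    n_blob = int(n * 0.8)
    k = rng.integers(2, 5)
    centers = rng.uniform(-1, 1, (k, 3))
    idx = rng.integers(0, k, n_blob)
    pts = centers[idx] + rng.normal(0, 0.05, (n_blob, 3))
    sparse = rng.uniform(-2, 2, (n - n_blob, 3))
    return pb.PointCloud(np.vstack([pts, sparse]))
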