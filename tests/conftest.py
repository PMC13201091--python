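import numpy as np
import pytest

from msprofiler.synth import (
    CohortConfig,
    generate_clinical,
    generate_label_volume,
    generate_tractogram,
)


@pytest.fixture(scope="session")
def small_labels():
    return generate_label_volume(n_regions=4, grid_shape=(16, 16, 16), region_size=20, seed=7)


@pytest.fixture(scope="session")
def small_tractogram(small_labels):
    return generate_tractogram(small_labels, streamlines_per_pair=5, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    clinical, truth = generate_clinical(CohortConfig(seed=11))
    return clinical, truth


def random_toy_tractogram(rng, n_regions, n_streamlines, shape=(8, 8, 8)):
    """Arbitrary voxel-path streamlines with random endpoint labels."""
    from msprofiler.dconn import Tractogram

    streamlines = []
    endpoints = []
    for _ in range(n_streamlines):
        length = rng.integers(1, 12)
        path = rng.integers(0, shape[0], size=(length, 3))
        streamlines.append(path)
        endpoints.append(rng.integers(1, n_regions + 1, size=2))
    return Tractogram(
        streamlines=streamlines,
        endpoints=np.array(endpoints),
        n_regions=n_regions,
        grid_shape=shape,
    )
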