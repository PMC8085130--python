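import numpy as np
import pytest

from chisel.synthetic import generate_scene, preset_spec


@pytest.fixture(scope="session")
def scene_separated():
    """1000x1000 iispv-preset scene with 30 well-separated nuclei (seed 7)."""
    return generate_scene(preset_spec("iispv", n_nuclei=30, cluster_fraction=0.0, seed=7))


@pytest.fixture(scope="session")
def scene_clustered_small():
    """Compact scene with clusters for splitting/eval tests."""
    return generate_scene(
        preset_spec("iispv", height=500, width=500, n_nuclei=30, cluster_fraction=0.4, seed=13)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def dumbbell():
    """Two r=15 disks with centers 24 px apart, merged into one component."""
    m = disk_mask((60, 90), (30, 33), 15) | disk_mask((60, 90), (30, 57), 15)
    return m


@pytest.fixture(scope="session")
def triple_blob():
    """Three overlapping r=10 disks in a row."""
    m = (
        disk_mask((60, 100), (30, 25), 10)
        | disk_mask((60, 100), (30, 41), 10)
        | disk_mask((60, 100), (30, 57), 10)
    )
    return m
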