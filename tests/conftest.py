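import numpy as np
import pytest

from coverchange import Grid, WorldSpec, generate_world


@pytest.fixture(scope="session")
def world_spec():
    return WorldSpec(grid=Grid(96, 96), seed=7)


@pytest.fixture(scope="session")
def bundle(world_spec):
    """One medium synthetic world shared by the integration-level tests."""
    return generate_world(world_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def checker_map():
    """Small deterministic map with all seven classes plus nodata."""
    from coverchange import ClassMap

    values = np.arange(64).reshape(8, 8) % 8  # codes 0..7, 0 = nodata
    return ClassMap(Grid(8, 8), values.astype(np.int64), "t0")
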