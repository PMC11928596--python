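import numpy as np
import pytest

from soilews import ScenarioConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """The default study-condition scene (20x20, 240 months), shared read-only."""
    return generate_scene(ScenarioConfig())


@pytest.fixture(scope="session")
def small_scene():
    """A fast 6x6 scene for structural tests."""
    return generate_scene(ScenarioConfig(grid_rows=6, grid_cols=6, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
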