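import numpy as np
import pytest

from cbctkit.phantom import (
    DeformationSpec,
    DegradationSpec,
    PhantomSpec,
    generate_phantom,
    make_pair,
)


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    return PhantomSpec(grid_shape=(16, 96, 128), spacing=(5.0, 2.0, 2.0), seed=11)


@pytest.fixture(scope="session")
def desk_phantom(desk_spec):
    return generate_phantom(desk_spec)


@pytest.fixture(scope="session")
def small_pair(desk_spec):
    """A moderately deformed, degraded pair shared by the cheaper tests."""
    return make_pair(
        desk_spec,
        DegradationSpec(seed=12),
        DeformationSpec(seed=13),
        bladder_diff_target=30.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
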