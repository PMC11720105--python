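import numpy as np
import pytest

from nhpnet import CohortSpec, MisalignmentModel, ShapeParams, generate_cohort, make_skull_proxy


@pytest.fixture(scope="session")
def default_mesh():
    return make_skull_proxy(ShapeParams())


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic cohort shared across pipeline tests."""
    spec = CohortSpec(
        n_train=4,
        n_val=2,
        n_test=3,
        misalignment=MisalignmentModel(seed=11),
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
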