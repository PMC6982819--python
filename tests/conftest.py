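import numpy as np
import pytest

from comgait.slip_model import SlipParams, TouchdownRefs, default_params


@pytest.fixture(scope="session")
def params() -> SlipParams:
    return default_params()


@pytest.fixture(scope="session")
def soft_params() -> SlipParams:
    """Softer spring used by the walking-shaped stance templates."""
    return default_params(dimensionless_k=9.0)


@pytest.fixture(scope="session")
def refs(params) -> TouchdownRefs:
    return TouchdownRefs.from_params(params, theta_hs=-0.35, c_hs=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 3 speeds, 11 rounds each; shared across tests."""
    from comgait.synthetic_data import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(n_subjects=3, n_steps=11, seed=7))


@pytest.fixture(scope="session")
def moderate_trial(soft_params):
    from comgait.synthetic_data import generate_walking_trial

    return generate_walking_trial(
        soft_params, speed=1.42, n_steps=12, seed=3
    )
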