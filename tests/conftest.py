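import numpy as np
import pytest

from brainpad import CohortGenerator, GeneratorConfig


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Desk-scale configuration used across unit tests."""
    return GeneratorConfig(
        seed=42, n_train=150, n_male=60, n_female=50,
        n_voxels_gm=30, n_voxels_wm=30, target_deaths=12,
    )


@pytest.fixture(scope="session")
def small_generator(small_config) -> CohortGenerator:
    return CohortGenerator(small_config)


@pytest.fixture(scope="session")
def small_test_cohort(small_generator):
    return small_generator.test_cohort()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
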