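import numpy as np
import pytest

from bbhmap import CohortSpec, generate_cohort, generate_template


@pytest.fixture(scope="session")
def template_atlas():
    """Default-resolution template space (64^3, 2 mm isotropic)."""
    return generate_template((64, 64, 64), 2.0)


@pytest.fixture(scope="session")
def small_template_atlas():
    """Coarse template space for fast tests (32^3, 4 mm isotropic)."""
    return generate_template((32, 32, 32), 4.0)


@pytest.fixture(scope="session")
def cohort(template_atlas):
    """One default 450-patient synthetic cohort (seed 7)."""
    _, atlas = template_atlas
    return generate_cohort(CohortSpec(seed=7), atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
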