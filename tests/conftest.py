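import numpy as np
import pytest

from ratcat import build_task, generate_cohort
from ratcat.simulate import CohortConfig


@pytest.fixture(scope="session")
def cohort():
    """One full synthetic cohort at the default study design (32 subjects)."""
    return generate_cohort(CohortConfig(), seed=7)


@pytest.fixture(scope="session")
def tasks():
    return {rot: build_task(rot) for rot in (0, 45, 90, 135)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
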