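import numpy as np
import pytest

from coda24 import CohortSpec, DEFAULT_PARTS, generate_cohort, pivot_basis


@pytest.fixture(scope="session")
def basis():
    return pivot_basis(DEFAULT_PARTS, "sleep")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort (69 children, 30 sDCD), fixed seed."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def positive_comps():
    """Random strictly positive daily compositions for oracle checks."""
    r = np.random.default_rng(7)
    x = r.lognormal(mean=np.log([430, 700, 230, 60]), sigma=0.25, size=(40, 4))
    return x * (1440.0 / x.sum(axis=1, keepdims=True))
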