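import numpy as np
import pytest

from bsunet.phantom import generate_cohort, small_params


@pytest.fixture(scope="session")
def small_cohort():
    """20 synthetic patients, 25 slices, 64x64 — the desk-scale study
    cohort."""
    return generate_cohort(20, small_params(), seed=123, total_slices=25)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
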