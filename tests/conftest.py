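import numpy as np
import pytest

from traumascore.synthetic import CohortSpec, simulate_registry

NO_MISSING = {k: 0.0 for k in ("spo2", "iss", "sbp", "rr", "gcs")}


@pytest.fixture(scope="session")
def complete_cohort():
    """A mid-sized complete synthetic cohort shared by read-only tests."""
    spec = CohortSpec(n=4000, seed=20170703, missingness=dict(NO_MISSING))
    return simulate_registry(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
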