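import numpy as np
import pytest

from icisurv.cohort import CohortSpec, generate_cohort
from icisurv.pipeline import run_arm
from icisurv.preprocess import split_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A trial-sized (n=93) synthetic cohort under the default conditions."""
    cohort, burden, truth = generate_cohort(CohortSpec(n_patients=93, seed=7))
    return cohort, burden, truth


@pytest.fixture(scope="session")
def trained_hybrid(default_cohort):
    """One trained hybrid arm on the default cohort (shared across tests)."""
    cohort, _, _ = default_cohort
    split = split_cohort(cohort["patient_id"].to_numpy(), seed=11)
    return cohort, split, run_arm(cohort, "hybrid", split, net_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
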