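import numpy as np
import pytest

from swaymetrics.simulate import CohortSimParams, SwaySimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_study():
    """One simulated 20-subject study shared by read-only tests."""
    sway = SwaySimParams(subject_count=20, trials_per_subject=2, rng_seed=42)
    cohort_params = CohortSimParams(rng_seed=43)
    traces, cohort, truth = simulate_cohort(sway, cohort_params)
    return {"sway": sway, "cohort_params": cohort_params, "traces": traces,
            "cohort": cohort, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
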