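import numpy as np
import pytest

from seqhorizon import GenerativeParams, simulate_experiment, trial_summary
from seqhorizon.events import ipi_frame


@pytest.fixture(scope="session")
def cohort_params() -> GenerativeParams:
    """Reduced cohort keeping the calibrated generative defaults: fewer
    participants/blocks for test runtime, all rates and effects unchanged."""
    return GenerativeParams(n_participants=10, blocks_per_day=4,
                            trials_per_block=18, seed=11)


@pytest.fixture(scope="session")
def cohort(cohort_params):
    return simulate_experiment(cohort_params)


@pytest.fixture(scope="session")
def summary(cohort):
    return trial_summary(cohort.frame, seq_length=cohort.params.seq_length)


@pytest.fixture(scope="session")
def ipis(cohort):
    return ipi_frame(cohort.frame, seq_length=cohort.params.seq_length)


@pytest.fixture(scope="session")
def noiseless_params() -> GenerativeParams:
    """Deterministic schedule: no noise, no errors, no first/last speed-up."""
    return GenerativeParams(noise_cv=0.0, press_error_rate=0.0,
                            first_last_discount=0.0,
                            participant_horizon_sd=0.0,
                            participant_speed_sd=0.0, eye_lead_sd=0.0,
                            horizon_slope_per_day=0.0, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
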