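import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_cohort():
    """Two subjects, 20/40/20 s phases — enough epochs to train on."""
    from datbio import CohortSpec, generate_cohort

    spec = CohortSpec(n_subjects=2, durations_s=(20.0, 40.0, 20.0), seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def mini_epochs(mini_cohort):
    from datbio import bandpass, epoch_signal

    epochs = []
    for rec in mini_cohort:
        epochs += epoch_signal(bandpass(rec.stabilized()), window_s=2.0)
    return epochs
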