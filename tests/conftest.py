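import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myoarm import pipeline
from myoarm.robot import CONDITIONS
from myoarm.subject import SubjectProfile, build_training_protocol, simulate_session

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile()


@pytest.fixture(scope="session")
def quick_protocol(profile):
    """Full 28-trial protocol at reduced 3 s trial length to keep the suite
    fast; the class structure and SNR are the defaults."""
    return build_training_protocol(profile, "both", seed=101,
                                   trial_duration_s=3.0)


@pytest.fixture(scope="session")
def quick_model(quick_protocol):
    return pipeline.train_from_recordings(quick_protocol)


@pytest.fixture(scope="session")
def sessions(profile, quick_model):
    """Two closed-loop trials per support condition for one subject."""
    return {c: simulate_session(profile, c, n_trials=2, seed=202,
                                model=quick_model)
            for c in CONDITIONS}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
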