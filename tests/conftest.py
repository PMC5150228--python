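import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eeglifespan import preprocess, synth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def trend():
    return synth.SpectralTrendModel()


@pytest.fixture(scope="session")
def profile():
    return synth.SubjectProfile(user_id="u0", age=42, sex=1, line_freq=60)


@pytest.fixture(scope="session")
def clean_session(profile, trend):
    """One artifact-free 120-s rendered session, fully preprocessed."""
    raw = synth.render_session(profile, trend, None, duration=120.0, seed=11)
    clean = preprocess.preprocess_session(raw)
    assert clean.verdict == preprocess.VERDICT_CLEAN
    return clean


@pytest.fixture(scope="session")
def small_cohort_sessions(trend):
    """Rendered raw sessions for a handful of users (both tasks)."""
    cfg = synth.CohortConfig(
        n_users=6, sessions_per_user=(1, 2), session_duration=30.0, seed=5
    )
    return synth.generate_cohort(cfg, trend, synth.ArtifactModel(epoch_rate=0.02))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
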