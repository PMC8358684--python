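import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pausemix as pm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_spec() -> pm.MixtureSpec:
    """The well-separated three-process truth used across recovery tests."""
    return pm.MixtureSpec([4.6, 5.8, 7.0], [0.45, 0.45, 0.45], [0.55, 0.30, 0.15])


@pytest.fixture(scope="session")
def fast_em() -> pm.EMConfig:
    """Lean EM settings for corpus-scale tests."""
    return pm.EMConfig(n_restarts=2, max_iter=300, tol=1e-6, seed=0)


@pytest.fixture(scope="session")
def small_corpus_config() -> pm.CorpusConfig:
    """A small but fully-featured synthetic corpus configuration."""
    return pm.CorpusConfig(n_essays=40, events_mean=80.0, events_dispersion=4.0, seed=11)


def make_essay(essay_id="e", n_pauses=50, strand1=3, strand3=3, n_chars=100, context="WithinWord"):
    pauses = [pm.PauseEvent(context, 100.0 + i) for i in range(n_pauses)]
    return pm.EssayRecord(essay_id, pauses, n_chars, strand1, strand3)


@pytest.fixture
def essay_factory():
    return make_essay
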