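import pytest
from hypothesis import HealthCheck, settings

from trialscreen import fixture_lexicon, fixture_trials
from trialscreen import nlp

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lexicon():
    return fixture_lexicon()


@pytest.fixture(scope="session")
def rules():
    return nlp.default_rules()


@pytest.fixture(scope="session")
def trials(lexicon):
    return fixture_trials(lexicon)


@pytest.fixture(scope="session")
def trials_by_id(trials):
    return {t.trial_id: t for t in trials}
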