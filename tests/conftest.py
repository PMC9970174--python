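import pytest
from hypothesis import HealthCheck, settings

import recovlex as rx

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return rx.bundled_example_lexicon()


@pytest.fixture(scope="session")
def fixture_corpora():
    """The hand-checked worked corpus (pre, post, expectations)."""
    return rx.idealized_fixture()


@pytest.fixture(scope="session")
def fixture_tagged(fixture_corpora, lexicon):
    pre, post, _ = fixture_corpora
    tpre = rx.tag_corpus(rx.normalize_corpus(pre), lexicon)
    tpost = rx.tag_corpus(rx.normalize_corpus(post), lexicon)
    return tpre, tpost
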