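import pytest

from xferlang.preprocess import CleaningConfig, clean_corpus, segment_corpus
from xferlang.reports import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_reports={"us": 250, "mr": 250}, seed=42)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    """250 reports per domain with ground truth; shared across the suite."""
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def tokenized(small_corpus):
    reports, _ = small_corpus
    return clean_corpus(segment_corpus(reports), CleaningConfig(min_frequency=2))


@pytest.fixture(scope="session")
def tokenized_by_domain(tokenized):
    out = {}
    for t in tokenized:
        out.setdefault(t.domain, []).append(t)
    return out


@pytest.fixture(scope="session")
def us_model(tokenized_by_domain):
    """A trained source-domain embedding model (reused by many tests)."""
    from xferlang.w2v import train_skipgram
    return train_skipgram(tokenized_by_domain["us"], dim=50, epochs=5,
                          min_count=2, seed=7, domain="us")
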