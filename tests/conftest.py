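import pytest

from condevol.engine import TranslatedSearchEngine


@pytest.fixture(scope="session")
def engine():
    """One shared built-in search engine (stateless between searches)."""
    return TranslatedSearchEngine()
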