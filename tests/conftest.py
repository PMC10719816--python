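import pytest
from hypothesis import settings

from emospect.lexicon import default_lexicon

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from emospect.sentiment import default_valence_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def valence():
    return default_valence_lexicon()
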