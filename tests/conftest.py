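import pytest
from hypothesis import HealthCheck, settings

from medrelex.resources import (
    default_lexicon,
    default_pattern_specs,
    default_patterns,
    default_schema,
)
from medrelex.segmentation import HeuristicPOSTagger

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def lexicon(schema):
    return default_lexicon(schema)


@pytest.fixture(scope="session")
def patterns(schema):
    return default_patterns(schema)


@pytest.fixture(scope="session")
def pattern_specs():
    return default_pattern_specs()


@pytest.fixture(scope="session")
def tagger():
    return HeuristicPOSTagger()
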