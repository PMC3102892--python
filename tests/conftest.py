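import hypothesis
import pytest

from hyeval.fixtures import (
    build_gal_fixture,
    gal_regulation_hypothesis,
    galactose_transport_hypothesis,
)
from hyeval.scoring import default_rulesets

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def gal():
    """(KnowledgeBase, TermStore) for the GAL fixture."""
    return build_gal_fixture()


@pytest.fixture(scope="session")
def gal_kb(gal):
    return gal[0]


@pytest.fixture(scope="session")
def gal_store(gal):
    return gal[1]


@pytest.fixture(scope="session")
def rulesets():
    return default_rulesets()


@pytest.fixture(scope="session")
def worked_hypothesis():
    return gal_regulation_hypothesis()


@pytest.fixture(scope="session")
def transport_hypothesis():
    return galactose_transport_hypothesis()
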