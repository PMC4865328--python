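import pytest

from belpipe.fixtures import FixtureBundle, worked_examples


@pytest.fixture(scope="session")
def bundle() -> FixtureBundle:
    return worked_examples()


@pytest.fixture(scope="session")
def resources(bundle):
    return bundle.resources()


@pytest.fixture(scope="session")
def trees(bundle):
    return bundle.parse_trees()


@pytest.fixture(scope="session")
def sentences(bundle):
    return dict(bundle.sentences)


@pytest.fixture(scope="session")
def protein_lexicon(resources):
    return resources.lexicons["protein"]
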