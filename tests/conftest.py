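import pytest

from eqtraits import fixtures as fx
from eqtraits.reasoner import classify


@pytest.fixture(scope="session")
def bundle():
    return fx.build_fixture_bundle()


@pytest.fixture(scope="session")
def refs(bundle):
    return bundle.reference_ontology()


@pytest.fixture(scope="session")
def traits(bundle):
    """Compiled trait ontology fragment (terms + EQ axioms + GCIs)."""
    return fx.compile_bundle_traits(bundle)


@pytest.fixture(scope="session")
def release(refs, traits):
    """References merged with compiled traits: the classifiable release."""
    return refs.merge(traits)


@pytest.fixture(scope="session")
def release_result(release):
    return classify(release)


@pytest.fixture(scope="session")
def merged_with_phenotypes(release, bundle):
    return release.merge(bundle.mini_phenotype)
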