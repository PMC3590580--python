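import pytest

from proteodendro import pipeline
from proteodendro.synth_fixtures import FixtureSpec, generate


@pytest.fixture(scope="session")
def fixture_set():
    """Benchmark fixture: 6 taxa, 10 planted families, 5% divergence."""
    return generate(FixtureSpec(seed=17))


@pytest.fixture(scope="session")
def build_result(fixture_set):
    """Full pipeline output (dedup -> clusters -> profiles -> NJ tree)."""
    return pipeline.build_tree(fixture_set.proteomes)


@pytest.fixture(scope="session")
def alien_set():
    """Proteomes drawn from a family pool disjoint from fixture_set's."""
    return generate(FixtureSpec(seed=90017, taxon_prefix="U"))
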