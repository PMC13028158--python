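import pytest

from fesnet import (
    GeneratorConfig,
    NetworkRules,
    generate_network,
    generate_species_set,
    load_fixture_groups,
    load_paper_fixture,
)


@pytest.fixture(scope="session")
def fmap():
    """The packaged transcribed free-energy map."""
    return load_paper_fixture()


@pytest.fixture(scope="session")
def groups():
    return load_fixture_groups()


@pytest.fixture(scope="session")
def synth_map():
    """A seeded synthetic map with TSs, consistent by construction."""
    species = generate_species_set(GeneratorConfig(n_species=12, seed=42))
    return generate_network(species, NetworkRules(n_reactions=10), seed=42)
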