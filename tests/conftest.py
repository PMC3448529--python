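import random

import pytest
from hypothesis import settings

import eqphen as eq
from eqphen import fixtures as fx

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog() -> fx.FixtureCatalog:
    return eq.build_mini_ontologies()


@pytest.fixture(scope="session")
def merged(catalog) -> eq.Ontology:
    return catalog.merged()


@pytest.fixture(scope="session")
def compiled(catalog, merged):
    return eq.compile_all(merged, catalog.union_definitions)


@pytest.fixture(scope="session")
def axioms(merged, compiled) -> eq.AxiomSet:
    equivalences, sufficient = compiled
    return eq.AxiomSet.from_ontology(
        merged, equivalences=equivalences, sufficient_conditions=sufficient
    )


@pytest.fixture(scope="session")
def defined(compiled) -> list[str]:
    equivalences, sufficient = compiled
    return sorted(set(equivalences) | set(sufficient))


@pytest.fixture(scope="session")
def qualifier_table():
    return eq.default_qualifier_table()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20260928)
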