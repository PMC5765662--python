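import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ontomod import MireotSpec, OntologyGraph, TermIRI
from ontomod.fixtures import (
    TAXON,
    make_obi_like_fixture,
    make_odp_fixture,
    make_taxonomy_fixture,
    make_vaccine_fixture,
)


@pytest.fixture
def taxonomy():
    return make_taxonomy_fixture()


@pytest.fixture
def species():
    """The three low-level input terms of the worked taxonomy example."""
    return frozenset(
        [TAXON["Homo sapiens"], TAXON["Mus musculus"], TAXON["Rattus norvegicus"]]
    )


@pytest.fixture
def target_superclass():
    return TermIRI("http://purl.example.org/target/Organism")


@pytest.fixture
def taxonomy_spec(taxonomy, species, target_superclass):
    def make(mode="no_intermediates", **kw):
        return MireotSpec(
            source=taxonomy,
            low_terms=species,
            top_term=TAXON["Root"],
            target_superclass=target_superclass,
            mode=mode,
            **kw,
        )

    return make


@pytest.fixture
def diamond():
    """D below both B and C, which are both below A; E below B only."""
    g = OntologyGraph(ontology_iri=TermIRI("http://example.org/diamond"))
    iris = {k: TermIRI(f"http://example.org/diamond#{k}") for k in "ABCDE"}
    for k, iri in iris.items():
        g.add_class(iri, k)
    g.add_edge(iris["B"], iris["A"])
    g.add_edge(iris["C"], iris["A"])
    g.add_edge(iris["D"], iris["B"])
    g.add_edge(iris["D"], iris["C"])
    g.add_edge(iris["E"], iris["B"])
    return g, iris


@pytest.fixture
def odp():
    return make_odp_fixture()


@pytest.fixture
def vo_like():
    return make_vaccine_fixture()


@pytest.fixture
def obi_like():
    return make_obi_like_fixture()
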