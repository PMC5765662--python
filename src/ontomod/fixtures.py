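"""Deterministic synthetic fixtures: every other module is testable offline.

The taxonomy fixture emulates the shape of the NCBI organismal taxonomy
around human, mouse and rat — deliberately built so that Murinae and
Euarchontoglires are the two pairwise minimal common ancestors of the
three species, giving the computed-intermediates extraction a known,
hand-checkable answer.  The adverse-event ODP fixture emulates a
two-row quick-term-template expansion against a small OAE/VO-like
support ontology.  Random DAGs provide property-test instances.

All IRIs here are synthetic stand-ins shaped like their OBO Foundry
counterparts; nothing is downloaded.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import (
    IAO_DEFINITION,
    RDFS_LABEL,
    AnnotationAssertion,
    OntologyGraph,
    TermIRI,
    UsageError,
)
from .templates import TemplateSettings, TemplateTable, parse_settings

__all__ = [
    "DagRecipe",
    "TAXON",
    "make_taxonomy_fixture",
    "make_random_dag",
    "make_odp_fixture",
    "make_vaccine_fixture",
    "make_obi_like_fixture",
]

_TAXON_BASE = "http://purl.obolibrary.org/obo/NCBITaxon_"

#: Term IRIs of the taxonomy fixture, keyed by label.
TAXON = {
    "Root": TermIRI(_TAXON_BASE + "1"),
    "Eukaryota": TermIRI(_TAXON_BASE + "2759"),
    "Euarchontoglires": TermIRI(_TAXON_BASE + "314146"),
    "Primates": TermIRI(_TAXON_BASE + "9443"),
    "Homo sapiens": TermIRI(_TAXON_BASE + "9606"),
    "Glires": TermIRI(_TAXON_BASE + "314147"),
    "Murinae": TermIRI(_TAXON_BASE + "39107"),
    "Mus musculus": TermIRI(_TAXON_BASE + "10090"),
    "Rattus norvegicus": TermIRI(_TAXON_BASE + "10116"),
}

_TAXON_EDGES = [
    ("Eukaryota", "Root"),
    ("Euarchontoglires", "Eukaryota"),
    ("Primates", "Euarchontoglires"),
    ("Homo sapiens", "Primates"),
    ("Glires", "Euarchontoglires"),
    ("Murinae", "Glires"),
    ("Mus musculus", "Murinae"),
    ("Rattus norvegicus", "Murinae"),
]


def make_taxonomy_fixture() -> OntologyGraph:
    """Nine labelled classes, eight edges: the human/mouse/rat lineage chain.

    Root ⊐ Eukaryota ⊐ Euarchontoglires ⊐ {Primates ⊐ Homo sapiens;
    Glires ⊐ Murinae ⊐ {Mus musculus, Rattus norvegicus}}.
    """
    g = OntologyGraph(ontology_iri=TermIRI("http://purl.example.org/ontomod/taxonomy"))
    for label, iri in TAXON.items():
        g.add_class(iri, label)
    for child, parent in _TAXON_EDGES:
        g.add_edge(TAXON[child], TAXON[parent])
    return g


@dataclass(frozen=True)
class DagRecipe:
    """Recipe for a random single-rooted DAG (integer-only randomness)."""

    n_terms: int
    extra_parent_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 2:
            raise UsageError("n_terms must be >= 2")
        if not 0.0 <= self.extra_parent_prob <= 1.0:
            raise UsageError("extra_parent_prob must be in [0, 1]")


def make_random_dag(recipe: DagRecipe) -> OntologyGraph:
    """Random single-rooted DAG: spanning-tree backbone plus extra edges.

    Node ``i`` (i ≥ 1) gets a uniformly chosen parent among nodes
    ``0..i-1``; with probability ``extra_parent_prob`` it gets one more
    distinct earlier parent.  Edges always point to earlier nodes, so the
    graph is acyclic by construction.  Structure decisions use integer
    draws only, so a fixed seed reproduces the same graph everywhere.
    """
    rng = random.Random(recipe.seed)
    base = "http://purl.example.org/ontomod/dag%d#" % recipe.seed
    g = OntologyGraph(ontology_iri=TermIRI(base.rstrip("#")))
    iris = [TermIRI(base + "T%d" % i) for i in range(recipe.n_terms)]
    for i, iri in enumerate(iris):
        g.add_class(iri, "term %d" % i)
    threshold = int(recipe.extra_parent_prob * 10_000)
    for i in range(1, recipe.n_terms):
        parent = rng.randrange(i)
        g.add_edge(iris[i], iris[parent])
        if i > 1 and rng.randrange(10_000) < threshold:
            extra = rng.randrange(i)
            if extra != parent:
                g.add_edge(iris[i], iris[extra])
    return g


# --------------------------------------------------------------------------
# Adverse-event ODP fixture
# --------------------------------------------------------------------------

_OBO = "http://purl.obolibrary.org/obo/"

_ODP_SETTINGS_YAML = """\
iri_base: http://purl.obolibrary.org/obo/OAE_
id_digits: 7
id_start: 1001
ontology_iri: http://purl.example.org/ontomod/oae-new-terms
label_rule:
  pattern: "{Label}"
annotations:
  - property: IAO:0000115
    pattern: "An adverse event in which {Label} occurs after administration of {Vaccine}."
axioms:
  - kind: subClassOf
    pattern: "'{Parent}'"
  - kind: subClassOf
    pattern: "'occurs after' some ('vaccination' and ('administers' some '{Vaccine}'))"
"""

_ODP_ROWS = [
    {
        "Label": "abdominal pain AE",
        "Parent": "discomfort AE",
        "Vaccine": "BCG vaccine",
    },
    {
        "Label": "injection site discomfort AE",
        "Parent": "discomfort AE",
        "Vaccine": "influenza vaccine",
    },
]


def make_odp_fixture():
    """Adverse-event ODP: settings, a two-row table, and a support ontology.

    The support ontology supplies the parent class ('discomfort AE'
    under 'adverse event'), the relation IRIs, and the vaccine fillers,
    so both the plain-parent axiom rule and the existential
    occurs-after rule resolve against it.
    """
    settings = parse_settings(_ODP_SETTINGS_YAML)
    table = TemplateTable(header=["Label", "Parent", "Vaccine"], rows=[dict(r) for r in _ODP_ROWS])

    support = OntologyGraph(
        ontology_iri=TermIRI("http://purl.example.org/ontomod/oae-support")
    )
    ae = support.add_class(TermIRI(_OBO + "OAE_0000001"), "adverse event")
    discomfort = support.add_class(TermIRI(_OBO + "OAE_0000081"), "discomfort AE")
    support.add_edge(discomfort, ae)
    vaccination = support.add_class(TermIRI(_OBO + "VO_0000002"), "vaccination")
    vaccine = support.add_class(TermIRI(_OBO + "VO_0000001"), "vaccine")
    bcg = support.add_class(TermIRI(_OBO + "VO_0000771"), "BCG vaccine")
    flu = support.add_class(TermIRI(_OBO + "VO_0000642"), "influenza vaccine")
    support.add_edge(bcg, vaccine)
    support.add_edge(flu, vaccine)
    occurs_after = TermIRI(_OBO + "RO_0002092")
    administers = TermIRI(_OBO + "RO_0002233")
    support.object_properties |= {occurs_after, administers}
    support.annotations.append(AnnotationAssertion(occurs_after, RDFS_LABEL, "occurs after"))
    support.annotations.append(AnnotationAssertion(administers, RDFS_LABEL, "administers"))
    support.annotations.append(
        AnnotationAssertion(
            discomfort,
            IAO_DEFINITION,
            "An adverse event in which a patient reports discomfort.",
        )
    )
    return settings, table, support


# --------------------------------------------------------------------------
# VO/OBI-like fixtures for axiom retrieval and reuse reporting
# --------------------------------------------------------------------------

def make_vaccine_fixture() -> OntologyGraph:
    """A VO-like graph: 'vaccine' asserted under an OBI-style parent.

    'vaccine' (VO_0000001) sits under 'processed material' (OBI_0000047),
    which is declared but carries only a label — the shape that exercises
    stub reporting in axiom retrieval.
    """
    g = OntologyGraph(ontology_iri=TermIRI("http://purl.example.org/ontomod/vo.owl"))
    vaccine = g.add_class(TermIRI(_OBO + "VO_0000001"), "vaccine")
    processed = g.add_class(TermIRI(_OBO + "OBI_0000047"), "processed material")
    g.add_edge(vaccine, processed)
    vaccination = g.add_class(TermIRI(_OBO + "VO_0000002"), "vaccination")
    administering = g.add_class(TermIRI(_OBO + "OBI_0600007"), "administering substance in vivo")
    g.add_edge(vaccination, administering)
    return g


def make_obi_like_fixture() -> OntologyGraph:
    """An OBI-like graph that reuses the VO 'vaccine' term by IRI."""
    g = OntologyGraph(ontology_iri=TermIRI("http://purl.example.org/ontomod/obi.owl"))
    material = g.add_class(TermIRI(_OBO + "OBI_0000047"), "processed material")
    vaccine = g.add_class(TermIRI(_OBO + "VO_0000001"), "vaccine")
    g.add_edge(vaccine, material)
    return g
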