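"""Term-reuse extraction: modes, intermediates, axiom retrieval, assembly."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontomod import (
    Existential,
    LogicalAxiom,
    MireotSpec,
    Named,
    OntologyGraph,
    TermIRI,
    ValidationError,
    ancestors,
    assemble_target,
    compute_intermediates,
    extract_subset,
    load_ontology,
    parse_extraction_spec,
    retrieve_axioms,
    save_ontology,
    validate_spec,
)
from ontomod.fixtures import TAXON, DagRecipe, make_random_dag
from ontomod.mireot import build_spec_from_text
from ontomod.model import IAO_IMPORTED_FROM, RDFS_LABEL

from oracles import brute_minimal_common_ancestors, closure_ancestors, reachable

OBO = "http://purl.obolibrary.org/obo/"


class TestValidateSpec:
    def test_complete_spec_passes(self, taxonomy_spec):
        assert validate_spec(taxonomy_spec()) == []

    @pytest.mark.parametrize(
        "field,value,expect",
        [
            ("target_superclass", "", "target direct superclass"),
            ("low_terms", frozenset(), "source term identifier"),
        ],
    )
    def test_missing_mireot_element_is_named(self, taxonomy_spec, field, value, expect):
        spec = taxonomy_spec()
        setattr(spec, field, value)
        report = validate_spec(spec)
        assert any(expect in v for v in report)

    def test_missing_source_ontology_identifier_is_named(self, taxonomy_spec):
        spec = taxonomy_spec()
        spec.source.ontology_iri = ""
        assert any("source ontology" in v for v in validate_spec(spec))

    def test_top_term_not_an_ancestor_names_the_term(self, taxonomy_spec):
        spec = taxonomy_spec()
        spec.top_term = TAXON["Primates"]  # not above mouse or rat
        report = validate_spec(spec)
        assert any(str(TAXON["Mus musculus"]) in v for v in report)
        assert not any(str(TAXON["Homo sapiens"]) in v for v in report)

    def test_extract_refuses_invalid_spec(self, taxonomy_spec):
        spec = taxonomy_spec(mode="banana")
        with pytest.raises(ValidationError):
            extract_subset(spec)


class TestComputeIntermediates:
    def test_worked_taxonomy_example(self, taxonomy, species):
        got = compute_intermediates(taxonomy, species, TAXON["Root"])
        assert got == {TAXON["Murinae"], TAXON["Euarchontoglires"]}
        assert got == brute_minimal_common_ancestors(
            taxonomy.subclass_edges, species, TAXON["Root"]
        )

    def test_single_low_term_has_no_pairs(self, taxonomy):
        assert compute_intermediates(taxonomy, [TAXON["Mus musculus"]], TAXON["Root"]) == set()

    def test_diamond_keeps_minimal_common_ancestor_only(self, diamond):
        g, iris = diamond
        got = compute_intermediates(g, [iris["D"], iris["E"]], iris["A"])
        assert got == {iris["B"]}

    def test_multiple_incomparable_minimal_ancestors_are_all_kept(self):
        # X and Y are both minimal common ancestors of the pair (C1, C2)
        g = OntologyGraph(ontology_iri=TermIRI("http://example.org/multi"))
        iri = {k: TermIRI(f"http://example.org/multi#{k}") for k in ["R", "X", "Y", "C1", "C2"]}
        for v in iri.values():
            g.add_class(v)
        g.add_edge(iri["X"], iri["R"])
        g.add_edge(iri["Y"], iri["R"])
        for c in ("C1", "C2"):
            g.add_edge(iri[c], iri["X"])
            g.add_edge(iri[c], iri["Y"])
        got = compute_intermediates(g, [iri["C1"], iri["C2"]], iri["R"])
        assert got == {iri["X"], iri["Y"]}


class TestExtractModes:
    def test_no_intermediates_is_plain_mireot(self, taxonomy_spec, species, target_superclass):
        result = extract_subset(taxonomy_spec("no_intermediates"))
        assert result.terms == set(species)
        assert result.edges == {(t, target_superclass) for t in species}

    def test_computed_intermediates_rebuilds_reduced_hierarchy(
        self, taxonomy_spec, species, target_superclass
    ):
        result = extract_subset(taxonomy_spec("computed_intermediates"))
        assert len(result.terms) == 5
        assert result.terms == set(species) | {TAXON["Murinae"], TAXON["Euarchontoglires"]}
        assert result.edges == {
            (TAXON["Mus musculus"], TAXON["Murinae"]),
            (TAXON["Rattus norvegicus"], TAXON["Murinae"]),
            (TAXON["Murinae"], TAXON["Euarchontoglires"]),
            (TAXON["Homo sapiens"], TAXON["Euarchontoglires"]),
            (TAXON["Euarchontoglires"], target_superclass),
        }

    def test_all_intermediates_is_the_ancestor_closure_below_root(
        self, taxonomy_spec, species
    ):
        result = extract_subset(taxonomy_spec("all_intermediates"))
        assert result.terms == set(species) | {
            TAXON["Primates"],
            TAXON["Murinae"],
            TAXON["Glires"],
            TAXON["Euarchontoglires"],
            TAXON["Eukaryota"],
        }
        assert len(result.terms) == 8

    def test_annotations_default_to_labels_and_definitions(self, taxonomy_spec):
        result = extract_subset(taxonomy_spec("no_intermediates"))
        assert {a.property for a in result.annotations} == {RDFS_LABEL}
        assert len(result.annotations) == 3

    def test_ancestor_low_term_serves_as_parent_in_the_reduction(
        self, taxonomy, target_superclass
    ):
        spec = MireotSpec(
            source=taxonomy,
            low_terms=frozenset([TAXON["Mus musculus"], TAXON["Murinae"]]),
            top_term=TAXON["Root"],
            target_superclass=target_superclass,
            mode="computed_intermediates",
        )
        result = extract_subset(spec)
        # Glires is the minimal common ancestor of the pair (Mus, Murinae)
        assert result.edges == {
            (TAXON["Mus musculus"], TAXON["Murinae"]),
            (TAXON["Murinae"], TAXON["Glires"]),
            (TAXON["Glires"], target_superclass),
        }


class TestRetrieveAxioms:
    def test_named_superclass_outside_set_becomes_axiom_plus_stub(self, vo_like):
        vaccine = TermIRI(OBO + "VO_0000001")
        axioms, stubs = retrieve_axioms(vo_like, [vaccine], "full_closure", depth=0)
        assert axioms == [
            LogicalAxiom("subClassOf", vaccine, Named(TermIRI(OBO + "OBI_0000047")))
        ]
        assert stubs == {TermIRI(OBO + "OBI_0000047")}

    def test_subclass_only_drops_axioms_mentioning_outsiders(self, vo_like):
        vaccine = TermIRI(OBO + "VO_0000001")
        axioms, stubs = retrieve_axioms(vo_like, [vaccine], "subclass_only")
        assert axioms == [] and stubs == set()

    def test_subclass_only_keeps_axioms_within_the_set(self, vo_like):
        vaccine = TermIRI(OBO + "VO_0000001")
        material = TermIRI(OBO + "OBI_0000047")
        axioms, _ = retrieve_axioms(vo_like, [vaccine, material], "subclass_only")
        assert LogicalAxiom("subClassOf", vaccine, Named(material)) in axioms

    def test_depth_one_promotes_first_layer_and_stubs_the_second(self):
        g = OntologyGraph(ontology_iri=TermIRI("http://example.org/chain"))
        a, b, c = (TermIRI(f"http://example.org/chain#{x}") for x in "abc")
        p, q = (TermIRI(f"http://example.org/chain#{x}") for x in "pq")
        for t in (a, b, c):
            g.add_class(t)
        g.object_properties |= {p, q}
        ax_a = LogicalAxiom("subClassOf", a, Existential(p, Named(b)))
        ax_b = LogicalAxiom("subClassOf", b, Existential(q, Named(c)))
        g.axioms += [ax_a, ax_b]
        axioms, stubs = retrieve_axioms(g, [a], "full_closure", depth=1)
        assert set(axioms) == {ax_a, ax_b}
        assert stubs == {c}  # properties never become stubs
        # depth 0 stops at the first layer
        axioms0, stubs0 = retrieve_axioms(g, [a], "full_closure", depth=0)
        assert set(axioms0) == {ax_a} and stubs0 == {b}


class TestAssembleTarget:
    def test_each_species_has_exactly_one_parent_the_target(
        self, taxonomy_spec, species, target_superclass
    ):
        spec = taxonomy_spec("no_intermediates")
        out = assemble_target(extract_subset(spec), spec)
        for s in species:
            parents = {p for c, p in out.subclass_edges if c == s}
            assert parents == {target_superclass}

    def test_every_imported_term_has_one_provenance_annotation(
        self, taxonomy_spec, species, taxonomy
    ):
        spec = taxonomy_spec("computed_intermediates")
        result = extract_subset(spec)
        out = assemble_target(result, spec)
        prov = [a for a in out.annotations if a.property == IAO_IMPORTED_FROM]
        assert {a.subject for a in prov} == result.terms
        assert all(a.value == str(taxonomy.ontology_iri) for a in prov)
        assert len(prov) == len(result.terms)

    def test_assembled_graph_round_trips(self, taxonomy_spec):
        spec = taxonomy_spec("all_intermediates")
        out = assemble_target(extract_subset(spec), spec)
        for fmt in ("turtle", "rdfxml"):
            back = load_ontology(io.BytesIO(save_ontology(out, fmt)), fmt)
            assert back == out

    def test_stub_terms_are_declared_with_labels_only(self, vo_like, target_superclass):
        spec = MireotSpec(
            source=vo_like,
            low_terms=frozenset([TermIRI(OBO + "VO_0000001")]),
            top_term=TermIRI(OBO + "VO_0000001"),
            target_superclass=target_superclass,
            mode="no_intermediates",
            axiom_mode="full_closure",
            axiom_depth=0,
        )
        result = extract_subset(spec)
        assert result.stub_terms == {TermIRI(OBO + "OBI_0000047")}
        out = assemble_target(result, spec)
        assert TermIRI(OBO + "OBI_0000047") in out.classes
        stub_ann = [a for a in out.annotations if a.subject == TermIRI(OBO + "OBI_0000047")]
        assert {a.property for a in stub_ann} == {RDFS_LABEL, IAO_IMPORTED_FROM}


class TestSpecDialect:
    TEXT = """\
[Source ontology]
taxonomy.ttl

[Low level source term URIs]
http://purl.obolibrary.org/obo/NCBITaxon_9606\tHomo sapiens
NCBITaxon:10090
http://purl.obolibrary.org/obo/NCBITaxon_10116

[Top level source term URIs and target direct superclass URIs]
NCBITaxon:1\thttp://purl.example.org/target/Organism

[Source term retrieval setting]
includeComputedIntermediates

[Source annotation URIs]
http://www.w3.org/2000/01/rdf-schema#label
"""

    def test_sections_parse_with_curie_resolution(self, taxonomy):
        prefixes = {"NCBITaxon": OBO + "NCBITaxon_"}
        fields = parse_extraction_spec(self.TEXT, prefixes)
        assert fields["source"] == "taxonomy.ttl"
        assert fields["low_terms"] == frozenset(
            [TAXON["Homo sapiens"], TAXON["Mus musculus"], TAXON["Rattus norvegicus"]]
        )
        assert fields["top_term"] == TAXON["Root"]
        assert fields["mode"] == "computed_intermediates"
        assert fields["annotation_properties"] == (RDFS_LABEL,)
        spec = build_spec_from_text(self.TEXT, taxonomy, prefixes)
        assert validate_spec(spec) == []

    def test_unknown_section_and_setting_are_rejected(self):
        with pytest.raises(ValidationError):
            parse_extraction_spec("[No such section]\n")
        bad = self.TEXT.replace("includeComputedIntermediates", "includeSome")
        with pytest.raises(ValidationError):
            parse_extraction_spec(bad, {})

    def test_include_all_annotations_marker(self):
        text = self.TEXT.replace(
            "http://www.w3.org/2000/01/rdf-schema#label", "includeAll"
        )
        fields = parse_extraction_spec(text, {"NCBITaxon": OBO + "NCBITaxon_"})
        assert fields["annotation_properties"] == "all"


# ---------------------------------------------------------------------------
# Property suites on random DAGs
# ---------------------------------------------------------------------------

def _random_case(seed):
    import random

    rng = random.Random(seed)
    n = rng.randint(4, 40)
    g = make_random_dag(DagRecipe(n, rng.uniform(0, 0.5), seed))
    classes = sorted(g.classes)
    root = next(iter(g.roots()))
    k = rng.randint(1, min(6, n - 1))
    low = frozenset(rng.sample([c for c in classes if c != root], k))
    return g, low, root


def _specs_for(g, low, root, seed):
    target = TermIRI("http://example.org/target#T")
    return {
        mode: MireotSpec(
            source=g, low_terms=low, top_term=root, target_superclass=target, mode=mode
        )
        for mode in ("no_intermediates", "computed_intermediates", "all_intermediates")
    }


@pytest.mark.parametrize("seed", range(200))
def test_computed_intermediates_match_brute_force_oracle(seed):
    g, low, root = _random_case(seed)
    got = compute_intermediates(g, low, root)
    want = brute_minimal_common_ancestors(g.subclass_edges, low, root)
    assert got == want


@pytest.mark.parametrize("seed", range(60))
def test_mode_monotonicity_and_structure(seed):
    """terms(no) ⊆ terms(computed) ⊆ terms(all); reachability in the output
    mirrors source ancestry; output edges form a transitive reduction; every
    extracted term keeps at least one parent."""
    g, low, root = _random_case(seed)
    specs = _specs_for(g, low, root, seed)
    results = {mode: extract_subset(spec) for mode, spec in specs.items()}

    t_no = results["no_intermediates"].terms
    t_comp = results["computed_intermediates"].terms
    t_all = results["all_intermediates"].terms
    assert t_no <= t_comp <= t_all

    target = specs["no_intermediates"].target_superclass
    for mode in ("computed_intermediates", "all_intermediates"):
        res = results[mode]
        internal = {(c, p) for c, p in res.edges if p != target}
        # subsumption preservation among extracted terms
        for a in res.terms:
            for b in res.terms:
                if a == b:
                    continue
                out_reach = reachable(internal, a, b)
                src_reach = b in closure_ancestors(g.subclass_edges, a)
                assert out_reach == src_reach, (mode, a, b)
        # transitive reduction: no edge is implied by the others
        for edge in internal:
            others = internal - {edge}
            assert not reachable(others, edge[0], edge[1]), (mode, edge)
        # connectivity: every extracted term has a parent in the output
        children = {c for c, _ in res.edges}
        assert res.terms <= children
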