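"""MIREOT-style term-reuse extraction.

Given a source ontology, a set of low-level terms of direct interest, a
top-level boundary term and a target direct superclass, produce a subset
module ready to merge into a target ontology.  Three retrieval settings
control which intermediate ancestors come along:

* ``no_intermediates`` — plain MIREOT: the requested terms only, each
  attached directly under the target superclass;
* ``computed_intermediates`` — additionally the minimal common ancestors
  of at least two requested terms (below the top boundary), with the
  hierarchy among the retained terms rebuilt as a transitive reduction;
* ``all_intermediates`` — every proper ancestor of a requested term that
  lies strictly below the top boundary.

Semantic axioms of the extracted terms can be carried along either
restricted to the extracted set (``subclass_only``) or as a bounded
closure that promotes referenced terms for a fixed number of rounds and
reports the remainder as stub declarations (``full_closure``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .model import (
    IAO_DEFINITION,
    IAO_IMPORTED_FROM,
    RDFS_LABEL,
    AnnotationAssertion,
    LogicalAxiom,
    Named,
    OntologyGraph,
    TermIRI,
    UsageError,
    ValidationError,
    ancestors,
    get_annotations,
)

__all__ = [
    "MODES",
    "AXIOM_MODES",
    "MireotSpec",
    "ExtractionResult",
    "validate_spec",
    "compute_intermediates",
    "retrieve_axioms",
    "extract_subset",
    "assemble_target",
    "parse_extraction_spec",
]

MODES = ("no_intermediates", "computed_intermediates", "all_intermediates")
AXIOM_MODES = ("none", "subclass_only", "full_closure")

#: Annotation properties copied when the caller does not list any:
#: label and textual definition, the minimal-annotation convention.
DEFAULT_ANNOTATION_PROPERTIES = (RDFS_LABEL, IAO_DEFINITION)


@dataclass
class MireotSpec:
    """One extraction request against a loaded source ontology.

    The three identifiers MIREOT requires — source ontology, source
    term(s), target direct superclass — are all mandatory and checked by
    :func:`validate_spec`.
    """

    source: OntologyGraph
    low_terms: frozenset
    top_term: TermIRI
    target_superclass: TermIRI
    mode: str = "no_intermediates"
    annotation_properties: Optional[tuple] = None  # None -> defaults; "all" -> every property seen
    axiom_mode: str = "subclass_only"
    axiom_depth: int = 1

    def resolved_annotation_properties(self) -> tuple:
        if self.annotation_properties is None:
            return DEFAULT_ANNOTATION_PROPERTIES
        if self.annotation_properties == "all":
            return tuple(sorted({a.property for a in self.source.annotations}))
        return tuple(self.annotation_properties)


@dataclass
class ExtractionResult:
    """The extracted subset, ready for :func:`assemble_target`."""

    terms: set = field(default_factory=set)
    edges: set = field(default_factory=set)  # (child, parent)
    annotations: list = field(default_factory=list)
    axioms: list = field(default_factory=list)
    stub_terms: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)  # term -> source ontology IRI


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def validate_spec(spec: MireotSpec) -> list:
    """Return the list of violated requirements (empty list = runnable).

    Checks the MIREOT minimal-information set (source ontology identifier,
    source term identifiers, target direct superclass identifier), the
    mode labels, membership of the terms in the source, and that the top
    boundary is an ancestor-or-self of every requested term.
    """
    violations: list = []
    if not spec.source or not getattr(spec.source, "ontology_iri", ""):
        violations.append("missing MIREOT element: source ontology identifier")
    if not spec.low_terms:
        violations.append("missing MIREOT element: source term identifier(s)")
    if not spec.target_superclass:
        violations.append("missing MIREOT element: target direct superclass identifier")
    if spec.mode not in MODES:
        violations.append(f"unknown retrieval mode: {spec.mode!r}")
    if spec.axiom_mode not in AXIOM_MODES:
        violations.append(f"unknown axiom mode: {spec.axiom_mode!r}")
    if spec.axiom_mode == "full_closure" and spec.axiom_depth < 0:
        violations.append("axiom closure depth must be >= 0")
    if not spec.source:
        return violations
    if not spec.top_term:
        violations.append("missing top-level boundary term")
        return violations
    if spec.top_term not in spec.source.classes:
        violations.append(f"top term not a class of the source: {spec.top_term}")
        return violations
    for t in sorted(spec.low_terms):
        if t not in spec.source.classes:
            violations.append(f"low-level term not a class of the source: {t}")
        elif t != spec.top_term and spec.top_term not in ancestors(spec.source, t):
            violations.append(
                f"top term {spec.top_term} is not an ancestor of low-level term {t}"
            )
    return violations


# --------------------------------------------------------------------------
# Intermediate computation
# --------------------------------------------------------------------------

def compute_intermediates(
    graph: OntologyGraph, low_terms: Iterable[TermIRI], top_term: TermIRI
) -> set:
    """Minimal common ancestors of at least two low terms, below ``top_term``.

    For every pair of distinct low terms the common proper ancestors are
    collected and only the minimal ones kept (those with no proper
    descendant that is also a common ancestor of the same pair).  The
    union over all pairs is returned, restricted to proper descendants of
    ``top_term`` and excluding the low terms themselves.  In a
    multi-parent DAG a pair may contribute several minimal common
    ancestors; all are kept.
    """
    low = [TermIRI(t) for t in low_terms]
    top = TermIRI(top_term)
    anc = {t: ancestors(graph, t) for t in low}
    below_top = set()
    for t in graph.classes:
        if t != top and top in ancestors(graph, t):
            below_top.add(t)
    out: set = set()
    for s1, s2 in itertools.combinations(sorted(set(low)), 2):
        common = anc[s1] & anc[s2]
        for a in common:
            # minimal: no proper descendant of a is also a common ancestor
            if not any(c != a and a in ancestors(graph, c) for c in common):
                out.add(a)
    return (out & below_top) - set(low)


def _transitive_reduction_edges(graph: OntologyGraph, retained: set) -> set:
    """Edges (child, parent) of the transitive reduction of the source
    ancestor relation restricted to ``retained``."""
    rel = nx.DiGraph()
    rel.add_nodes_from(retained)
    for a in retained:
        ups = ancestors(graph, a) & retained
        for b in ups:
            rel.add_edge(a, b)
    red = nx.transitive_reduction(rel)
    return set(red.edges())


# --------------------------------------------------------------------------
# Axiom retrieval
# --------------------------------------------------------------------------

def _axioms_of(graph: OntologyGraph, subject: TermIRI, include_edge_axioms: bool) -> list:
    out = [ax for ax in graph.axioms if ax.subject == subject]
    if include_edge_axioms:
        out.extend(
            LogicalAxiom("subClassOf", c, Named(p))
            for c, p in sorted(graph.subclass_edges)
            if c == subject
        )
    return out


def retrieve_axioms(
    graph: OntologyGraph,
    terms: Iterable[TermIRI],
    axiom_mode: str,
    depth: int = 1,
    include_edge_axioms: bool = True,
):
    """Collect logical axioms for ``terms`` per the axiom mode.

    ``subclass_only`` keeps axioms whose subject is in ``terms`` and whose
    expression mentions (in class position) only members of ``terms``.
    ``full_closure`` keeps every axiom of the terms; class IRIs mentioned
    outside the set are promoted for ``depth`` rounds (their own axioms
    pulled in turn) and whatever is still unresolved after the last round
    is returned as the stub set.  Object properties never become stubs.

    Named-superclass axioms are synthesized from subclass edges when
    ``include_edge_axioms`` is true, so a term asserted under a named
    class outside the set surfaces as an axiom plus a stub.

    Returns ``(axioms, stub_terms)``.
    """
    term_set = {TermIRI(t) for t in terms}
    if not term_set:
        raise UsageError("retrieve_axioms requires a non-empty term set")
    if axiom_mode == "none":
        return [], set()
    if axiom_mode == "subclass_only":
        kept = []
        for t in sorted(term_set):
            for ax in _axioms_of(graph, t, include_edge_axioms):
                if ax.expression.class_iris() <= term_set:
                    kept.append(ax)
        return kept, set()
    if axiom_mode != "full_closure":
        raise UsageError(f"unknown axiom mode: {axiom_mode!r}")
    if depth < 0:
        raise UsageError("closure depth must be >= 0")

    collected: list = []
    known = set(term_set)
    frontier = sorted(term_set)
    stubs: set = set()
    for level in range(depth + 1):
        mentioned: set = set()
        for t in frontier:
            for ax in _axioms_of(graph, t, include_edge_axioms):
                collected.append(ax)
                mentioned |= ax.expression.class_iris()
        new = {m for m in mentioned if m not in known}
        if level == depth:
            stubs = new
            break
        known |= new
        frontier = sorted(m for m in new if m in graph.classes)
        stubs = new - set(frontier)  # mentioned but unknown to the source
        if not frontier:
            break
    return collected, stubs


# --------------------------------------------------------------------------
# Extraction
# --------------------------------------------------------------------------

def extract_subset(spec: MireotSpec) -> ExtractionResult:
    """Run one extraction request; see module docstring for the modes."""
    violations = validate_spec(spec)
    if violations:
        raise ValidationError("; ".join(violations))

    graph = spec.source
    low = {TermIRI(t) for t in spec.low_terms}
    top = TermIRI(spec.top_term)
    target = TermIRI(spec.target_superclass)
    result = ExtractionResult()

    if spec.mode == "no_intermediates":
        result.terms = set(low)
        result.edges = {(t, target) for t in sorted(low)}
    else:
        if spec.mode == "computed_intermediates":
            extra = compute_intermediates(graph, low, top)
        else:  # all_intermediates
            extra = set()
            for t in low:
                extra |= {a for a in ancestors(graph, t) if a != top and top in ancestors(graph, a) | {a}}
            extra -= {top}
            extra -= low
        retained = low | extra
        result.terms = retained
        result.edges = _transitive_reduction_edges(graph, retained)
        children = {c for c, _ in result.edges}
        for r in sorted(retained):
            if r not in children:
                result.edges.add((r, target))

    props = spec.resolved_annotation_properties()
    if props:
        result.annotations = get_annotations(graph, result.terms, props)

    if spec.axiom_mode != "none":
        axioms, stubs = retrieve_axioms(
            graph,
            result.terms,
            spec.axiom_mode,
            depth=spec.axiom_depth,
            include_edge_axioms=(spec.axiom_mode == "full_closure"),
        )
        # Hierarchy among extracted terms is exactly the mode-defined edge
        # set; drop named-superclass axioms pointing back inside it.
        axioms = [
            ax
            for ax in axioms
            if not (
                ax.kind == "subClassOf"
                and isinstance(ax.expression, Named)
                and ax.expression.iri in result.terms
            )
        ]
        result.axioms = axioms
        result.stub_terms = stubs - result.terms
        promoted = {ax.subject for ax in axioms} - result.terms
        if promoted:
            result.terms |= promoted
            if props:
                result.annotations.extend(get_annotations(graph, promoted, props))
        # stubs carry labels only by default
        if result.stub_terms:
            result.annotations.extend(
                get_annotations(graph, result.stub_terms & graph.classes, [RDFS_LABEL])
            )

    for t in sorted(result.terms | result.stub_terms):
        result.provenance[t] = graph.ontology_iri
    return result


def assemble_target(
    result: ExtractionResult,
    spec: MireotSpec,
    ontology_iri: Optional[TermIRI] = None,
    provenance_property: TermIRI = IAO_IMPORTED_FROM,
) -> OntologyGraph:
    """Build a standalone ontology holding the extracted subset.

    The target superclass is declared; every imported term (including
    stubs) carries one provenance annotation naming its source ontology.
    """
    iri = TermIRI(ontology_iri or (spec.source.ontology_iri + "-subset"))
    out = OntologyGraph(ontology_iri=iri)
    out.add_class(TermIRI(spec.target_superclass))
    for t in sorted(result.terms | result.stub_terms):
        out.classes.add(TermIRI(t))
    for c, p in sorted(result.edges):
        out.add_edge(c, p)
    out.annotations.extend(result.annotations)
    for ax in result.axioms:
        out.add_axiom(ax)
    for prop in sorted({p for ax in result.axioms for p in ax.expression.property_iris()}):
        out.object_properties.add(prop)
    out.annotation_properties.add(TermIRI(provenance_property))
    for t in sorted(result.provenance):
        out.annotations.append(
            AnnotationAssertion(TermIRI(t), TermIRI(provenance_property), str(result.provenance[t]))
        )
    out.check_acyclic()
    return out


# --------------------------------------------------------------------------
# Sectioned plain-text input dialect
# --------------------------------------------------------------------------

_SECTION_ALIASES = {
    "source ontology": "source",
    "low level source term uris": "low_terms",
    "top level source term uris and target direct superclass uris": "top_and_target",
    "source term retrieval setting": "setting",
    "source annotation uris": "annotations",
}

_SETTING_NAMES = {
    "includenointermediates": "no_intermediates",
    "includecomputedintermediates": "computed_intermediates",
    "includeallintermediates": "all_intermediates",
}


def _resolve(token: str, prefixes: dict) -> TermIRI:
    token = token.strip()
    if ":" in token:
        pfx, _, local = token.partition(":")
        if pfx in prefixes:
            return TermIRI(prefixes[pfx] + local)
    return TermIRI(token)


def parse_extraction_spec(text: str, prefixes: Optional[dict] = None) -> dict:
    """Parse the sectioned plain-text extraction dialect.

    Sections: ``[Source ontology]`` (path or IRI), ``[Low level source
    term URIs]`` (one IRI per line, optional label after a tab), ``[Top
    level source term URIs and target direct superclass URIs]`` (one
    ``top<TAB>superclass`` pair), ``[Source term retrieval setting]``,
    ``[Source annotation URIs]`` (IRIs or ``includeAll``).  Returns a
    dict of the parsed fields; pair it with a loaded source graph to
    build a :class:`MireotSpec`.
    """
    prefixes = prefixes or {}
    sections: dict = {}
    current = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip().lower()
            if name not in _SECTION_ALIASES:
                raise ValidationError(f"line {lineno}: unknown section [{line[1:-1]}]")
            current = _SECTION_ALIASES[name]
            sections.setdefault(current, [])
            continue
        if current is None:
            raise ValidationError(f"line {lineno}: content before any section header")
        sections[current].append((lineno, line))

    out: dict = {}
    src = sections.get("source", [])
    out["source"] = src[0][1] if src else None

    out["low_terms"] = frozenset(
        _resolve(line.split("\t")[0], prefixes) for _, line in sections.get("low_terms", [])
    )

    pairs = sections.get("top_and_target", [])
    if not pairs:
        out["top_term"] = None
        out["target_superclass"] = None
    else:
        lineno, line = pairs[0]
        parts = [p for p in line.split("\t") if p.strip()]
        if len(parts) != 2:
            raise ValidationError(
                f"line {lineno}: expected 'top<TAB>target superclass', got {line!r}"
            )
        out["top_term"] = _resolve(parts[0], prefixes)
        out["target_superclass"] = _resolve(parts[1], prefixes)

    setting = sections.get("setting", [])
    if setting:
        lineno, name = setting[0]
        key = name.strip().lower()
        if key not in _SETTING_NAMES:
            raise ValidationError(f"line {lineno}: unknown retrieval setting {name!r}")
        out["mode"] = _SETTING_NAMES[key]
    else:
        out["mode"] = "no_intermediates"

    ann = sections.get("annotations", [])
    if not ann:
        out["annotation_properties"] = None
    elif any(line.strip().lower() == "includeall" for _, line in ann):
        out["annotation_properties"] = "all"
    else:
        out["annotation_properties"] = tuple(
            _resolve(line.split("\t")[0], prefixes) for _, line in ann
        )
    return out


def build_spec_from_text(
    text: str, source: OntologyGraph, prefixes: Optional[dict] = None, **overrides
) -> MireotSpec:
    """Convenience: parse the text dialect and bind it to a loaded source."""
    fields = parse_extraction_spec(text, prefixes)
    fields.pop("source", None)
    fields.update(overrides)
    return MireotSpec(source=source, **fields)
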