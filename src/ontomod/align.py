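"""Multi-ontology alignment and duplicate reporting.

Aligns two or three ontologies from their roots and reports: per-ontology
term inventories, the terms shared by each combination of inputs (IRI
identity — reuse), duplicate-label candidates (same normalized label,
different IRIs — redundancy), and simple structural warnings (multiple
roots, redundant subclass edges).  Reuse and redundancy are deliberately
kept apart: a term reused under the same IRI is interoperability working
as intended, while two IRIs sharing a label are candidates for manual
reconciliation.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import (
    RDFS_LABEL,
    OntologyGraph,
    TermIRI,
    UsageError,
    ancestors,
)

__all__ = [
    "AlignmentReport",
    "ReuseReport",
    "align",
    "duplicate_labels",
    "reuse_report",
    "redundant_edges",
    "normalize_label",
]

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Case-fold, strip and collapse internal whitespace."""
    return _WS.sub(" ", label.strip()).casefold()


@dataclass
class AlignmentReport:
    ontology_ids: list
    term_sets: dict  # ontology IRI -> set[TermIRI]
    shared: dict  # tuple(sorted combo) -> set[TermIRI]
    duplicate_labels: list  # [(normalized label, [(ontology IRI, TermIRI), ...])]
    multi_root_warnings: dict = field(default_factory=dict)
    redundant_edge_warnings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ontology_ids": [str(o) for o in self.ontology_ids],
            "term_sets": {str(o): sorted(map(str, s)) for o, s in self.term_sets.items()},
            "shared": {
                " & ".join(combo): sorted(map(str, terms))
                for combo, terms in self.shared.items()
            },
            "duplicate_labels": [
                {"label": label, "terms": [[str(o), str(t)] for o, t in pairs]}
                for label, pairs in self.duplicate_labels
            ],
            "multi_root_warnings": {
                str(o): sorted(map(str, roots))
                for o, roots in self.multi_root_warnings.items()
            },
            "redundant_edge_warnings": {
                str(o): [[str(c), str(p)] for c, p in edges]
                for o, edges in self.redundant_edge_warnings.items()
            },
        }


def redundant_edges(graph: OntologyGraph) -> list:
    """Asserted edges (child, parent) already implied through another parent."""
    out = []
    for child, parent in sorted(graph.subclass_edges):
        others = {p for c, p in graph.subclass_edges if c == child and p != parent}
        if any(parent == o or parent in ancestors(graph, o) for o in others):
            out.append((child, parent))
    return out


def align(graphs: list) -> AlignmentReport:
    """Align 2–3 ontologies: shared-term sets per combination, plus warnings."""
    if not 2 <= len(graphs) <= 3:
        raise UsageError(f"align takes 2 or 3 ontologies, got {len(graphs)}")
    ids = [g.ontology_iri for g in graphs]
    if len(set(ids)) != len(ids):
        raise UsageError("ontology IRIs must be distinct")
    term_sets = {g.ontology_iri: set(g.classes) for g in graphs}
    shared = {}
    for size in (2, 3):
        for combo in itertools.combinations(sorted(ids), size):
            if size <= len(ids):
                sets = [term_sets[i] for i in combo]
                shared[combo] = set.intersection(*sets)
    report = AlignmentReport(
        ontology_ids=list(ids),
        term_sets=term_sets,
        shared=shared,
        duplicate_labels=duplicate_labels(graphs),
    )
    for g in graphs:
        roots = g.roots()
        if len(roots) > 1:
            report.multi_root_warnings[g.ontology_iri] = roots
        redundant = redundant_edges(g)
        if redundant:
            report.redundant_edge_warnings[g.ontology_iri] = redundant
    return report


def duplicate_labels(graphs: Iterable[OntologyGraph]) -> list:
    """Group distinct IRIs that share a normalized label, within or across
    ontologies.  The same IRI labelled identically in two ontologies is
    reuse, not redundancy, and is not reported."""
    graphs = list(graphs)
    if not graphs:
        raise UsageError("duplicate_labels requires at least one ontology")
    by_label: dict = {}
    for g in graphs:
        for a in g.annotations:
            if a.property == RDFS_LABEL and a.subject in g.classes:
                by_label.setdefault(normalize_label(a.value), set()).add(
                    (g.ontology_iri, a.subject)
                )
    out = []
    for label in sorted(by_label):
        pairs = by_label[label]
        distinct_iris = {iri for _, iri in pairs}
        if len(distinct_iris) >= 2:
            out.append((label, sorted(pairs)))
    return out


@dataclass
class ReuseReport:
    term: TermIRI
    native: list  # ontologies owning the term's namespace that declare it
    reusers: list  # other ontologies declaring it


def _owns_namespace(graph: OntologyGraph, term: TermIRI, prefixes: Optional[Mapping]) -> bool:
    """Does this ontology's namespace own the term IRI?

    With a prefix table ({ontology IRI -> term prefix}) ownership is an
    explicit prefix match; otherwise it is inferred by comparing the
    term's OBO-style ``PFX_`` prefix with the ontology IRI's basename
    (e.g. ``.../obo/vo.owl`` owns ``.../obo/VO_*``).
    """
    if prefixes and graph.ontology_iri in prefixes:
        return str(term).startswith(str(prefixes[graph.ontology_iri]))
    m = re.search(r"([A-Za-z][A-Za-z0-9]*)_[^/_]*$", str(term))
    if not m:
        return False
    stem = re.sub(r"\.(owl|ttl|rdf)$", "", str(graph.ontology_iri).rstrip("/").rsplit("/", 1)[-1])
    return m.group(1).casefold() == stem.casefold()


def reuse_report(
    graphs: Iterable[OntologyGraph],
    term: TermIRI,
    prefixes: Optional[Mapping] = None,
) -> ReuseReport:
    """Which ontologies declare ``term``, split into native owner(s) and reusers."""
    graphs = list(graphs)
    if not graphs:
        raise UsageError("reuse_report requires at least one ontology")
    term = TermIRI(term)
    native, reusers = [], []
    for g in graphs:
        if term in g.classes:
            (native if _owns_namespace(g, term, prefixes) else reusers).append(
                g.ontology_iri
            )
    return ReuseReport(term=term, native=native, reusers=reusers)
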