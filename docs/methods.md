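# Methods

## The ontology model

`ontomod` operates on asserted structure only. An ontology is held as a
typed graph: a set of named classes, a set of asserted subclass edges
between named classes, multisets of annotation assertions (literal
values with optional language tags) and logical axioms, and inventories
of object and annotation properties. The supported logical fragment is
`subClassOf` / `equivalentTo` whose right-hand side is built from named
classes, intersections (≥ 2 operands, order preserved) and existential
restrictions. This covers the axiom shapes that term-reuse workflows in
OBO-style ontologies traffic in (e.g. a vaccine class asserted under a
processed-material parent, or an adverse-event class defined by an
`occurs after` existential) while keeping parsing and round-tripping
exactly testable. Any other OWL construct encountered on load —
universal restrictions, cardinalities, unions, datatyped annotation
structures — is skipped and tallied in a load report; nothing is
silently dropped.

Two deliberate normalizations:

* **Canonical subclass form.** A `subClassOf` axiom whose right-hand
  side is a bare named class is stored as a subclass edge and never kept
  in the axiom multiset. The structural view (edges) and logical view
  (axioms) therefore cannot disagree, and `load(save(g)) == g` holds on
  all graph fields. Operations that need the axiom view of an edge
  (axiom retrieval) synthesize it on demand.
* **IRI identity.** Term IRIs are NFC-normalized strings compared by
  identity; no CURIE expansion happens in the model. CURIEs are resolved
  against a prefix table at the CLI/settings boundary only.

Cycles in the asserted subclass relation are a hard load error (the DAG
operations below are undefined on cycles); the error message lists one
offending cycle. Hierarchies are *asserted*, never reasoned: the
toolkit takes no position on inferred subsumption, and no description-
logic reasoner is involved.

Serialization is rdflib-backed (RDF/XML and Turtle). Triples are added
in sorted order, and expression bnodes are only ever referenced once, so
serializing the same graph twice is byte-identical.

## Term-reuse extraction

A reuse request carries the MIREOT minimal information — source
ontology identifier, source term identifiers, target direct superclass —
plus a top boundary term, a retrieval mode, annotation properties and an
axiom mode. The validator reports every violated requirement (missing
minimal element, unknown mode, terms absent from the source, top term
not an ancestor-or-self of each requested term) rather than stopping at
the first.

**Computed intermediates** are formalized as *pairwise minimal common
ancestors*: for every pair of distinct requested terms, the common
proper ancestors are enumerated and those with no proper descendant that
is also a common ancestor of the same pair are kept; the union over
pairs is restricted to proper descendants of the top term and excludes
the requested terms themselves. In a multi-parent DAG a pair may have
several incomparable minimal common ancestors — all are kept, with no
order-based tie-breaking. The top term itself is never emitted; the
target superclass supplies the attachment point.

**Edges** in the computed/all modes are the transitive reduction of the
source ancestor relation restricted to the retained terms (networkx's
reduction of the explicit reachability relation); a retained term with
several incomparable retained ancestors gets an edge to each. Retained
terms with no retained ancestor attach to the target superclass. A
requested term that is an ancestor of another requested term is allowed
and participates in the reduction like any retained term.

**Axiom retrieval.** `subclass_only` keeps axioms whose subject is
extracted and whose expression mentions, in class position, only
extracted terms. `full_closure` with depth *d* pulls all axioms of the
extracted terms, then promotes class IRIs mentioned outside the set for
*d* rounds (pulling their axioms in turn); whatever is still unresolved
after the last round is imported as a **stub** — a bare declaration with
label only. Object properties mentioned in restrictions are declared in
the output but never become stubs and never disqualify an axiom from
`subclass_only`; treating relations like class terms would make almost
every existential axiom unextractable. Within a full extraction,
named-superclass axioms whose parent is itself an extracted term are
dropped from the axiom channel: the hierarchy among extracted terms is
exactly the mode-defined edge set, and keeping both would smuggle the
source hierarchy into the flat MIREOT mode. Defaults: `subclass_only`,
closure depth 1 (one layer of promotion, no recursion blow-up).

**Assembly** produces a standalone ontology: the target superclass
declared, the extracted terms, edges, annotations and axioms, and one
provenance annotation per imported term (stubs included) naming the
source ontology. The provenance property defaults to the standard
"imported from" annotation (IAO 0000412) and is configurable. When no
annotation properties are requested, label and textual definition
(IAO 0000115) are copied — the minimal-annotation convention.

## Template expansion

A pattern string mixes literal text with `{Column}` placeholders
(`{{`/`}}` escape literal braces). A rule whose placeholders are all
empty for a row is skipped for that row; a rule mixing empty and
non-empty placeholders is an error rather than a silent partial string.
Settings default to 7-digit zero-padded identifiers starting at 1 —
the OBO numbering convention; minting is strictly row-order based, so
inserting a row shifts all later auto-assigned IDs (use an explicit IRI
column when identifiers must be stable). Exceeding the digit capacity is
an error, not a wider identifier.

Axiom patterns are parsed after interpolation with a small recursive-
descent parser over the grammar `expr := atom | expr 'and' expr | atom
'some' expr | '(' expr ')'`; `and` is left-associative and flattened
into a single intersection, `some` binds tighter than `and`. Atoms are
single-quoted labels resolved against a label→IRI table (user-supplied
mappings plus the labels of loaded support ontologies; a label carried
by two IRIs is ambiguous and errors), CURIEs, or angle-bracketed IRIs.
Labels minted earlier in the same expansion are immediately resolvable,
so later rows may reference earlier rows' terms.

Tables are CSV/TSV (UTF-8, RFC 4180 quoting) with an XLSX reader for
convenience; duplicate labels across rows are permitted, duplicate IRIs
never. Expansion is a pure function of (settings, table, resolver):
repeated runs serialize byte-identically.

**Merging** unions classes, edges and property inventories; annotation
and axiom multisets are unioned with exact-duplicate collapsing, which
makes merging idempotent and associative. The merged ontology keeps the
base's ontology IRI and records the terms present on both sides. An IRI
typed as a class on one side and an object property on the other is a
hard type-clash error.

## Alignment

"Common terms" means IRI identity — reuse of the same term — and is
computed as exact set intersections for every pair and triple of inputs.
Label matching is reported separately as *duplication candidates*:
distinct IRIs whose labels coincide after case-folding, stripping and
whitespace collapsing (no stemming or synonym expansion — semantic
matching is out of scope). Structural warnings are limited to multiple
roots and redundant edges (a class asserted under two comparable
parents). Native-namespace ownership for the reuse report is an explicit
ontology-IRI→prefix table when given, otherwise inferred by matching the
term's OBO-style `PFX_` prefix against the ontology IRI's basename.

## Synthetic fixtures and what they show

All inputs are generated in-process; the suite runs with networking
disabled.

* The **taxonomy fixture** (9 labelled classes, 8 edges) mirrors the
  organismal lineage around human, mouse and rat, deliberately shaped so
  the two pairwise minimal common ancestors of the species set are
  Murinae and Euarchontoglires — making the computed-intermediates
  setting hand-checkable without downloading the real taxonomy.
* The **adverse-event ODP fixture** is a two-row quick-term-template
  with label, parent and vaccine columns, one definition rule, one
  named-parent axiom rule and one nested existential rule, against a
  small OAE/VO-like support ontology.
* **Random DAGs** are single-rooted: a spanning-tree backbone (node *i*
  picks a uniform parent among `0..i-1`) plus one extra earlier parent
  with a configurable probability (default sizes n ≤ 40 in the property
  suites, 200 seeds for the oracle-equivalence check — small enough to
  run the whole suite in seconds, large enough to exercise multi-parent
  reductions). Structure decisions use integer draws only, so fixed
  seeds reproduce identical graphs across platforms.

These fixtures exercise the algorithms' combinatorics, not the mess of
real releases: no deprecated-term conventions, no imports closure, no
punning, no non-literal annotation structures, and label sets far
smaller than a real ontology's. Passing tests show the extraction,
expansion and alignment semantics are correct on the supported fragment;
they do not certify behaviour on OWL constructs outside it (which are
skipped with counts on load).

## Numerical and degenerate-input choices

* Equality of graphs compares class/edge/property sets and annotation/
  axiom multisets; list order never matters.
* A single requested term has no pairs, so computed intermediates are
  empty and the term attaches directly to the target superclass.
* An empty template table expands to an ontology with no new classes.
* `align` requires two or three inputs with distinct ontology IRIs;
  self-comparison is done on a copy with a fresh IRI.
* Exit codes: 0 success, 1 validation/data error, 2 usage error.

## Known limitations

Asserted hierarchies only (no reasoning); the restricted OWL fragment
above; no OBO flat-file parsing; no remote fetching of source
ontologies; template expansion cannot edit or delete existing terms; no
lexical/semantic mapping beyond normalized-label equality.
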