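# ontomod

An offline toolkit for **extensible ontology development**: reuse terms
from existing ontologies instead of re-inventing them, carry their
semantics along, generate batches of new terms from design patterns, and
audit the result for redundancy — all on local OWL files, with no web
services.

It is aimed at ontology engineers in the biomedical space (OBO-style
ontologies such as VO, OBI, OAE, NCBITaxon) who want the computational
cores of the familiar web tools — subset extraction, spreadsheet-to-OWL
template expansion, multi-ontology comparison — as a scriptable library
and command line.

## What it computes

**Term-reuse extraction (MIREOT).** A reuse request is the minimal
triple *(source ontology, source term(s), target direct superclass)*.
Given low-level terms *L*, a top boundary *t* and the asserted subclass
DAG of the source, the extractor supports three settings:

- `includeNoIntermediates` — plain MIREOT: exactly *L*, each term
  attached directly under the target superclass;
- `includeComputedIntermediates` — additionally every **minimal common
  ancestor** of a pair of requested terms: the set
  ⋃ over pairs s₁≠s₂ ∈ L of min≼ { a : a ≻ s₁ and a ≻ s₂ }, restricted
  strictly below *t*, where ≻ is the transitive closure of the asserted
  subclass relation and min≼ keeps ancestors with no common-ancestor
  proper descendant for the same pair. The hierarchy among retained
  terms is re-emitted as the transitive reduction of the restricted
  ancestor relation;
- `includeAllIntermediates` — every proper ancestor of a requested term
  strictly below *t*.

Semantic axioms of the extracted terms (subclass-of-restriction,
equivalences over intersections and existentials) can be carried along
either restricted to the extracted set, or as a bounded closure of depth
*d* that promotes referenced terms for *d* rounds and imports the rest
as labelled **stub** declarations.

**Design-pattern expansion.** An ontology design pattern is captured as
a settings file (IRI-minting rule plus annotation/axiom rules whose
patterns interpolate `{Column}` placeholders) and a table with one row
per new term. Expansion mints IRIs in row order, instantiates each rule,
parses axiom patterns as Manchester-style class expressions
(`atom`, `expr and expr`, `atom some expr`, parentheses), and emits an
OWL file ready to merge into the target ontology.

**Alignment and duplicate reporting.** Two or three ontologies are
aligned from their roots: shared-term sets for every combination (IRI
identity = reuse), duplicate-label candidates (same normalized label,
different IRIs = redundancy), multiple-root and redundant-edge warnings,
and a per-term reuse report.

## Worked example

The packaged taxonomy fixture reproduces the shape of the organismal
taxonomy around human, mouse and rat. Extracting those three species
with computed intermediates:

```sh
ontomod fixtures --taxonomy taxonomy.ttl --odp odp
ontomod extract --spec spec.txt --out subset.ttl
ontomod expand --settings odp/odp.yaml --table odp/rows.csv \
               --support odp/support.ttl --out new_terms.ttl
ontomod merge --base odp/support.ttl --add new_terms.ttl --out merged.ttl
ontomod align --onto merged.ttl --onto new_terms.ttl --report report.json
```

prints

```
taxonomy fixture -> taxonomy.ttl
ODP fixture -> odp/
extracted 5 terms -> subset.ttl
expanded 2 rows -> new_terms.ttl
merged 1 ontologies into odp/support.ttl -> merged.ttl
aligned 2 ontologies -> report.json
```

The five extracted terms are the three species plus their two pairwise
minimal common ancestors, Murinae (shared by mouse and rat) and
Euarchontoglires (shared by human with each rodent); `subset.ttl` shows
mouse and rat as direct children of Murinae, and human and Murinae as
direct children of Euarchontoglires, which hangs under the requested
target superclass. Each imported term carries an "imported from"
provenance annotation naming the source ontology. The expansion stage
turns the two table rows into two new adverse-event classes, each with
a label, a textual definition, a named parent and an existential
`occurs after` axiom; the merge resolves those parents against the
support ontology, and the alignment report lists the terms the merged
ontology now shares with the expansion output.

The same spec file drives the plain-MIREOT setting
(`includeNoIntermediates`, 3 terms flat under the target) and the full
closure (`includeAllIntermediates`, 8 terms — every ancestor below the
root).

Library use mirrors the CLI: `load_ontology` / `save_ontology`,
`MireotSpec` + `extract_subset` + `assemble_target`, `parse_settings` +
`expand_template` + `merge_ontologies`, `align` / `duplicate_labels` /
`reuse_report`, and `make_taxonomy_fixture` / `make_odp_fixture` /
`make_random_dag` for synthetic inputs.

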