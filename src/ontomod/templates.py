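"""Design-pattern template expansion: settings + populated table -> OWL.

An ontology design pattern (ODP) is captured as a settings document — an
IRI-minting rule plus ordered annotation and axiom rules whose patterns
interpolate table columns — and a table with one row per new term.
Expansion mints one new class per row, instantiates each rule against
the row's cells, parses axiom patterns as Manchester-style class
expressions, and returns an ontology ready to merge into an existing
one.

Identifier assignment is row-order based: inserting a row shifts the
auto-assigned IDs of every later row.  Use an explicit IRI column when
stable identifiers matter.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .model import (
    IAO_DEFINITION,
    RDFS_LABEL,
    AnnotationAssertion,
    ClassExpression,
    Existential,
    Intersection,
    LogicalAxiom,
    Named,
    OntologyGraph,
    OntomodError,
    TermIRI,
    UsageError,
)

__all__ = [
    "SettingsError",
    "PatternError",
    "ExpressionError",
    "ExpansionError",
    "MergeError",
    "EMPTY",
    "TemplateSettings",
    "TemplateTable",
    "LabelResolver",
    "parse_settings",
    "read_table",
    "next_iri",
    "instantiate_pattern",
    "parse_class_expression",
    "expand_template",
    "merge_ontologies",
]


class SettingsError(OntomodError):
    """The settings document is malformed."""


class PatternError(OntomodError):
    """A pattern string is malformed or references a missing column."""


class ExpressionError(OntomodError):
    """A class-expression string violates the grammar or names an unknown term."""


class ExpansionError(OntomodError):
    """Template expansion failed (duplicate IRIs, per-row rule errors)."""


class MergeError(OntomodError):
    """Two ontologies disagree on the type of a shared IRI."""


class _EmptySentinel:
    """Returned by pattern instantiation when every placeholder was empty."""

    def __repr__(self):  # pragma: no cover
        return "EMPTY"

    def __bool__(self):
        return False


EMPTY = _EmptySentinel()


# --------------------------------------------------------------------------
# Settings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationRule:
    property: TermIRI
    pattern: str


@dataclass(frozen=True)
class AxiomRule:
    kind: str  # subClassOf | equivalentTo
    pattern: str


@dataclass
class TemplateSettings:
    iri_base: str
    id_digits: int = 7
    id_start: int = 1
    explicit_iri_column: Optional[str] = None
    label_rule: tuple = (RDFS_LABEL, "{Label}")  # (property, pattern)
    annotation_rules: list = field(default_factory=list)
    axiom_rules: list = field(default_factory=list)
    ontology_iri: TermIRI = TermIRI("http://purl.example.org/ontomod/expansion")
    prefixes: dict = field(default_factory=dict)

    def referenced_columns(self) -> set:
        cols: set = set()
        for _, pat in [self.label_rule]:
            cols |= {name for _, name in _compile_pattern(pat) if name is not None}
        for rule in self.annotation_rules:
            cols |= {name for _, name in _compile_pattern(rule.pattern) if name is not None}
        for rule in self.axiom_rules:
            cols |= {name for _, name in _compile_pattern(rule.pattern) if name is not None}
        return cols


_SETTINGS_KEYS = {
    "iri_base",
    "id_digits",
    "id_start",
    "iri_column",
    "label_rule",
    "annotations",
    "axioms",
    "ontology_iri",
    "prefixes",
}

#: Prefixes understood out of the box in settings documents and CLI input.
DEFAULT_PREFIXES = {
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "IAO": "http://purl.obolibrary.org/obo/IAO_",
    "OBI": "http://purl.obolibrary.org/obo/OBI_",
    "OAE": "http://purl.obolibrary.org/obo/OAE_",
    "VO": "http://purl.obolibrary.org/obo/VO_",
    "RO": "http://purl.obolibrary.org/obo/RO_",
    "NCBITaxon": "http://purl.obolibrary.org/obo/NCBITaxon_",
}


def resolve_curie(token: str, prefixes: Mapping) -> TermIRI:
    """Expand ``PFX:local`` against a prefix table; pass full IRIs through."""
    token = token.strip()
    if token.startswith("<") and token.endswith(">"):
        return TermIRI(token[1:-1])
    pfx, sep, local = token.partition(":")
    if sep and pfx in prefixes:
        return TermIRI(prefixes[pfx] + local)
    return TermIRI(token)


def parse_settings(document: Union[str, Mapping]) -> TemplateSettings:
    """Parse a YAML settings document into :class:`TemplateSettings`.

    Omitted ``id_digits`` / ``id_start`` default to 7 and 1.  Unknown
    keys and malformed patterns are rejected with the offending key path.
    """
    if isinstance(document, str):
        try:
            data = yaml.safe_load(document)
        except yaml.YAMLError as exc:
            raise SettingsError(f"settings document is not valid YAML: {exc}") from exc
    else:
        data = dict(document)
    if not isinstance(data, dict):
        raise SettingsError("settings document must be a mapping")
    unknown = set(data) - _SETTINGS_KEYS
    if unknown:
        raise SettingsError("unknown settings keys: " + ", ".join(sorted(unknown)))
    if not data.get("iri_base"):
        raise SettingsError("missing required key: iri_base")

    prefixes = dict(DEFAULT_PREFIXES)
    prefixes.update(data.get("prefixes") or {})

    def check_pattern(pat, path):
        try:
            _compile_pattern(str(pat))
        except PatternError as exc:
            raise SettingsError(f"{path}: {exc}") from exc
        return str(pat)

    label_prop, label_pat = RDFS_LABEL, "{Label}"
    lr = data.get("label_rule")
    if lr is not None:
        if isinstance(lr, str):
            label_pat = check_pattern(lr, "label_rule")
        elif isinstance(lr, dict) and set(lr) <= {"property", "pattern"}:
            if "property" in lr:
                label_prop = resolve_curie(str(lr["property"]), prefixes)
            label_pat = check_pattern(lr.get("pattern", "{Label}"), "label_rule.pattern")
        else:
            raise SettingsError("label_rule: expected a pattern or {property, pattern}")

    annotation_rules = []
    for i, item in enumerate(data.get("annotations") or []):
        if not isinstance(item, dict) or set(item) != {"property", "pattern"}:
            raise SettingsError(f"annotations[{i}]: expected {{property, pattern}}")
        annotation_rules.append(
            AnnotationRule(
                resolve_curie(str(item["property"]), prefixes),
                check_pattern(item["pattern"], f"annotations[{i}].pattern"),
            )
        )

    axiom_rules = []
    for i, item in enumerate(data.get("axioms") or []):
        if not isinstance(item, dict) or set(item) != {"kind", "pattern"}:
            raise SettingsError(f"axioms[{i}]: expected {{kind, pattern}}")
        kind = str(item["kind"])
        if kind not in ("subClassOf", "equivalentTo"):
            raise SettingsError(f"axioms[{i}].kind: unknown kind {kind!r}")
        axiom_rules.append(
            AxiomRule(kind, check_pattern(item["pattern"], f"axioms[{i}].pattern"))
        )

    id_digits = int(data.get("id_digits", 7))
    id_start = int(data.get("id_start", 1))
    if id_digits < 1:
        raise SettingsError("id_digits must be >= 1")
    if id_start < 0:
        raise SettingsError("id_start must be >= 0")

    settings = TemplateSettings(
        iri_base=str(data["iri_base"]),
        id_digits=id_digits,
        id_start=id_start,
        explicit_iri_column=data.get("iri_column"),
        label_rule=(label_prop, label_pat),
        annotation_rules=annotation_rules,
        axiom_rules=axiom_rules,
        prefixes=prefixes,
    )
    if data.get("ontology_iri"):
        settings.ontology_iri = TermIRI(str(data["ontology_iri"]))
    return settings


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

@dataclass
class TemplateTable:
    """A populated template: one row per new term."""

    header: list
    rows: list  # list[dict[str, str]]

    def __post_init__(self):
        if len(set(self.header)) != len(self.header):
            raise UsageError("duplicate column names in table header")
        for i, row in enumerate(self.rows):
            if set(row) != set(self.header):
                raise UsageError(f"row {i + 1} does not match the header columns")


def read_table(source, fmt: Optional[str] = None) -> TemplateTable:
    """Read a CSV/TSV (or XLSX) table; format inferred from the extension."""
    if fmt is None:
        name = str(getattr(source, "name", source))
        fmt = "xlsx" if name.endswith(".xlsx") else ("tsv" if name.endswith(".tsv") else "csv")
    if fmt == "xlsx":
        from openpyxl import load_workbook

        ws = load_workbook(source, read_only=True).active
        cells = [[("" if c is None else str(c)) for c in row] for row in ws.iter_rows(values_only=True)]
    else:
        delim = "\t" if fmt == "tsv" else ","
        if hasattr(source, "read"):
            text = source.read()
            if isinstance(text, bytes):
                text = text.decode("utf-8")
        else:
            with open(source, "r", encoding="utf-8", newline="") as fh:
                text = fh.read()
        cells = list(csv.reader(io.StringIO(text), delimiter=delim))
    cells = [row for row in cells if any(c.strip() for c in row)]
    if not cells:
        raise UsageError("table has no header row")
    header = [c.strip() for c in cells[0]]
    rows = []
    for raw in cells[1:]:
        padded = list(raw) + [""] * (len(header) - len(raw))
        rows.append({h: padded[i].strip() for i, h in enumerate(header)})
    return TemplateTable(header=header, rows=rows)


# --------------------------------------------------------------------------
# IRI minting and pattern instantiation
# --------------------------------------------------------------------------

def next_iri(settings: TemplateSettings, ordinal: int) -> TermIRI:
    """Mint the IRI for the ``ordinal``-th new term (zero-padded numeric id)."""
    if ordinal < 0:
        raise UsageError("ordinal must be >= 0")
    number = settings.id_start + ordinal
    if len(str(number)) > settings.id_digits:
        raise ExpansionError(
            f"identifier {number} does not fit in {settings.id_digits} digit(s)"
        )
    return TermIRI(settings.iri_base + str(number).zfill(settings.id_digits))


_TOKEN_RE = re.compile(r"\{\{|\}\}|\{([^{}]*)\}|[^{}]+|\{|\}")


def _compile_pattern(pattern: str):
    """Split a pattern into (literal, None) and (None, column) segments."""
    segments = []
    pos = 0
    for m in _TOKEN_RE.finditer(pattern):
        tok = m.group(0)
        if tok == "{{":
            segments.append(("{", None))
        elif tok == "}}":
            segments.append(("}", None))
        elif tok in ("{", "}"):
            raise PatternError(f"unbalanced brace at offset {m.start()} in {pattern!r}")
        elif m.group(1) is not None:
            name = m.group(1).strip()
            if not name:
                raise PatternError(f"empty placeholder at offset {m.start()} in {pattern!r}")
            segments.append((None, name))
        else:
            segments.append((tok, None))
        pos = m.end()
    if pos != len(pattern):  # pragma: no cover - regex covers all chars
        raise PatternError(f"cannot tokenize pattern {pattern!r}")
    return segments


def instantiate_pattern(pattern: str, row: Mapping):
    """Fill a pattern from a table row.

    Returns the instantiated string, or :data:`EMPTY` when every
    placeholder maps to an empty cell (the caller skips the rule for that
    row).  Mixing empty and non-empty placeholders is an error rather
    than a silent partial string.
    """
    segments = _compile_pattern(pattern)
    names = [name for _, name in segments if name is not None]
    for name in names:
        if name not in row:
            raise PatternError(f"placeholder {{{name}}} names a missing column")
    if names:
        empties = [not str(row[name]).strip() for name in names]
        if all(empties):
            return EMPTY
        if any(empties):
            missing = sorted({n for n, e in zip(names, empties) if e})
            raise PatternError(
                "placeholders with empty cells mixed with filled ones: "
                + ", ".join(missing)
            )
    return "".join(lit if lit is not None else str(row[name]).strip() for lit, name in segments)


# --------------------------------------------------------------------------
# Manchester-style class-expression parser
# --------------------------------------------------------------------------

class LabelResolver:
    """Resolves quoted labels, CURIEs and IRIs to :class:`TermIRI`.

    Built from an optional user-supplied label→IRI mapping plus the
    labels of loaded support ontologies.  A label carried by two distinct
    IRIs is ambiguous and raises on lookup.
    """

    def __init__(self, labels: Optional[Mapping] = None, prefixes: Optional[Mapping] = None):
        self._labels: dict = {}
        self.prefixes = dict(prefixes or DEFAULT_PREFIXES)
        for label, iri in (labels or {}).items():
            self.add_label(label, TermIRI(iri))

    def add_label(self, label: str, iri: TermIRI) -> None:
        self._labels.setdefault(label, set()).add(TermIRI(iri))

    @classmethod
    def from_graphs(
        cls,
        graphs: Iterable[OntologyGraph],
        prefixes: Optional[Mapping] = None,
        extra_labels: Optional[Mapping] = None,
    ) -> "LabelResolver":
        resolver = cls(extra_labels, prefixes)
        for g in graphs:
            for a in g.annotations:
                if a.property == RDFS_LABEL:
                    resolver.add_label(a.value, a.subject)
        return resolver

    def resolve_label(self, label: str) -> TermIRI:
        hits = self._labels.get(label, set())
        if not hits:
            raise ExpressionError(f"unknown label: {label!r}")
        if len(hits) > 1:
            raise ExpressionError(
                f"ambiguous label {label!r}: " + ", ".join(sorted(hits))
            )
        return next(iter(hits))

    def resolve_atom(self, token: str) -> TermIRI:
        return resolve_curie(token, self.prefixes)


_EXPR_TOKEN = re.compile(
    r"\s*(?:(?P<quoted>'(?:[^'\\]|\\.)*')|(?P<lpar>\()|(?P<rpar>\))|(?P<word>[^\s()]+))"
)


def _tokenize_expression(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _EXPR_TOKEN.match(text, pos)
        if not m or m.end() == pos:
            raise ExpressionError(f"cannot tokenize at position {pos}: {text[pos:]!r}")
        if m.group("quoted"):
            label = m.group("quoted")[1:-1].replace("\\'", "'")
            tokens.append(("label", label, m.start()))
        elif m.group("lpar"):
            tokens.append(("(", "(", m.start()))
        elif m.group("rpar"):
            tokens.append((")", ")", m.start()))
        else:
            word = m.group("word")
            if word in ("and", "some"):
                tokens.append((word, word, m.start()))
            else:
                tokens.append(("atom", word, m.start()))
        pos = m.end()
    return tokens


class _ExpressionParser:
    """Recursive-descent parser: ``and`` is flattened into one intersection,
    ``some`` binds tighter than ``and``."""

    def __init__(self, tokens, resolver: LabelResolver, text: str):
        self.tokens = tokens
        self.i = 0
        self.resolver = resolver
        self.text = text

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise ExpressionError(f"unexpected end of expression: {self.text!r}")
        self.i += 1
        return tok

    def parse(self) -> ClassExpression:
        expr = self.expression()
        tok = self._peek()
        if tok is not None:
            raise ExpressionError(
                f"unexpected token {tok[1]!r} at position {tok[2]} in {self.text!r}"
            )
        return expr

    def expression(self) -> ClassExpression:
        operands = [self.primary()]
        while self._peek() and self._peek()[0] == "and":
            self._next()
            operands.append(self.primary())
        if len(operands) == 1:
            return operands[0]
        flat = []
        for op in operands:
            if isinstance(op, Intersection):
                flat.extend(op.operands)
            else:
                flat.append(op)
        return Intersection(tuple(flat))

    def primary(self) -> ClassExpression:
        tok = self._next()
        if tok[0] == "(":
            inner = self.expression()
            closing = self._next()
            if closing[0] != ")":
                raise ExpressionError(
                    f"expected ')' at position {closing[2]} in {self.text!r}"
                )
            return inner
        if tok[0] == "label":
            atom = self.resolver.resolve_label(tok[1])
        elif tok[0] == "atom":
            try:
                atom = self.resolver.resolve_atom(tok[1])
            except UsageError as exc:
                raise ExpressionError(
                    f"unresolvable atom {tok[1]!r} at position {tok[2]}: {exc}"
                ) from exc
        else:
            raise ExpressionError(
                f"unexpected token {tok[1]!r} at position {tok[2]} in {self.text!r}"
            )
        if self._peek() and self._peek()[0] == "some":
            self._next()
            return Existential(atom, self.primary())
        return Named(atom)


def parse_class_expression(text: str, resolver: LabelResolver) -> ClassExpression:
    """Parse ``atom | expr 'and' expr | atom 'some' expr | (expr)`` text.

    Atoms are single-quoted labels (resolved by ``resolver``), CURIEs or
    IRIs.  ``and`` is left-associative and flattened; ``some`` binds
    tighter than ``and``.
    """
    tokens = _tokenize_expression(text)
    if not tokens:
        raise ExpressionError("empty class expression")
    return _ExpressionParser(tokens, resolver, text).parse()


# --------------------------------------------------------------------------
# Expansion
# --------------------------------------------------------------------------

def expand_template(
    settings: TemplateSettings,
    table: TemplateTable,
    resolver: Optional[LabelResolver] = None,
) -> OntologyGraph:
    """Expand an ODP template: one new class per table row.

    Per row: the label rule, each non-empty annotation rule, and each
    non-empty axiom rule (parsed as a class expression) are instantiated.
    External terms referenced by axioms are declared in the output but
    not otherwise described.  Expansion is a pure function of its inputs;
    re-running it yields byte-identical serialized output.
    """
    resolver = resolver or LabelResolver(prefixes=settings.prefixes)
    missing = settings.referenced_columns() - set(table.header)
    if missing:
        raise ExpansionError(
            "patterns reference columns absent from the table: " + ", ".join(sorted(missing))
        )
    if settings.explicit_iri_column and settings.explicit_iri_column not in table.header:
        raise ExpansionError(
            f"iri_column {settings.explicit_iri_column!r} absent from the table"
        )

    out = OntologyGraph(ontology_iri=settings.ontology_iri)
    minted: list = []
    label_prop, label_pat = settings.label_rule
    for idx, row in enumerate(table.rows):
        rowno = idx + 1
        try:
            if settings.explicit_iri_column:
                raw = row[settings.explicit_iri_column].strip()
                iri = resolve_curie(raw, settings.prefixes) if raw else next_iri(settings, idx)
            else:
                iri = next_iri(settings, idx)
            if iri in out.classes:
                raise ExpansionError(f"duplicate term IRI {iri}")
            out.classes.add(iri)
            minted.append(iri)

            label = instantiate_pattern(label_pat, row)
            if label is not EMPTY:
                out.annotations.append(AnnotationAssertion(iri, label_prop, label))
                resolver.add_label(label, iri)
            for rule in settings.annotation_rules:
                value = instantiate_pattern(rule.pattern, row)
                if value is not EMPTY:
                    out.annotations.append(AnnotationAssertion(iri, rule.property, value))
                    out.annotation_properties.add(rule.property)
            for rule in settings.axiom_rules:
                text = instantiate_pattern(rule.pattern, row)
                if text is EMPTY:
                    continue
                expr = parse_class_expression(text, resolver)
                out.add_axiom(LogicalAxiom(rule.kind, iri, expr))
        except ExpansionError:
            raise
        except OntomodError as exc:
            raise ExpansionError(f"row {rowno}: {exc}") from exc

    # declare referenced external terms
    referenced: set = set()
    properties: set = set()
    for ax in out.axioms:
        referenced |= ax.expression.class_iris()
        properties |= ax.expression.property_iris()
    for _, parent in out.subclass_edges:
        referenced.add(parent)
    out.classes |= referenced
    out.object_properties |= properties
    out.check_acyclic()
    return out


# --------------------------------------------------------------------------
# Merging
# --------------------------------------------------------------------------

def merge_ontologies(base: OntologyGraph, addition: OntologyGraph) -> OntologyGraph:
    """Merge ``addition`` into ``base`` (ontology IRI taken from base).

    Class/edge/property sets are unioned; annotation and axiom multisets
    are unioned with exact-duplicate collapsing, which makes merging
    idempotent and associative.  Terms present in both inputs are listed
    on the result as ``merge_report``.  The same IRI typed as a class on
    one side and a property on the other is a hard error.
    """
    clash = (base.classes & addition.object_properties) | (
        addition.classes & base.object_properties
    )
    if clash:
        raise MergeError(
            "IRI(s) typed as class and object property: " + ", ".join(sorted(clash))
        )
    out = OntologyGraph(ontology_iri=base.ontology_iri)
    out.classes = set(base.classes) | set(addition.classes)
    out.subclass_edges = set(base.subclass_edges) | set(addition.subclass_edges)
    out.object_properties = set(base.object_properties) | set(addition.object_properties)
    out.annotation_properties = set(base.annotation_properties) | set(
        addition.annotation_properties
    )
    out.annotations = list(base.annotations)
    seen_ann = set(base.annotations)
    for a in addition.annotations:
        if a not in seen_ann:
            out.annotations.append(a)
            seen_ann.add(a)
    out.axioms = list(base.axioms)
    seen_ax = set(base.axioms)
    for ax in addition.axioms:
        if ax not in seen_ax:
            out.axioms.append(ax)
            seen_ax.add(ax)
    out.merge_report = sorted(base.classes & addition.classes)
    out.check_acyclic()
    return out
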