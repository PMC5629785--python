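"""R2RML mapping documents: parsing, the typed mapping model, and the
template algebra (expansion / inversion) used throughout the engine.

An R2RML document is a Turtle file in the ``rr:`` vocabulary.  Each
``rr:TriplesMap`` pairs a *logical table* (base table, SQL view, or inline
SQL query) with a *subject map* and a set of *predicate-object maps*.  Term
maps come in three kinds — constant, column, and template — and this module
implements the algebra over them that both the query translator and the
materializer rely on:

* :func:`referenced_columns` — which columns a term map reads;
* :func:`expand_template` — row values -> RDF term (the R2RML NULL rule:
  any NULL referenced column suppresses the term);
* :func:`invert_template` — RDF term -> column values, used to push
  constant subjects/objects of triple patterns down to SQL equality
  conditions on the underlying columns.

Templates use the standard curly-brace placeholder syntax
(``http://.../Patient/{patientId}``); ``\\{`` escapes a literal brace.
"""

from __future__ import annotations

import re
import urllib.parse
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import rdflib
from rdflib import RDF, BNode, Graph, Literal, URIRef
from rdflib.namespace import Namespace

RR = Namespace("http://www.w3.org/ns/r2rml#")
XSD = rdflib.XSD

__all__ = [
    "RR",
    "MappingError",
    "MappingValidationError",
    "TemplateNotInvertibleError",
    "LogicalTable",
    "TermMap",
    "RefObjectMap",
    "PredicateObjectMap",
    "TriplesMap",
    "MappingDocument",
    "parse_mapping",
    "serialize_mapping",
    "parse_template",
    "referenced_columns",
    "expand_template",
    "invert_template",
]


class MappingError(Exception):
    """Base class for mapping-level failures."""


class MappingValidationError(MappingError):
    """Structurally invalid mapping (missing subject map, dangling parent...)."""


class TemplateNotInvertibleError(MappingError):
    """Template whose expansion cannot be uniquely inverted (adjacent
    placeholders with no separator between them)."""


# --------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class LogicalTable:
    kind: str  # base_table | sql_view | sql_query
    name_or_query: str

    def __post_init__(self) -> None:
        if not self.name_or_query:
            raise MappingValidationError("logical table name/query is empty")


@dataclass(frozen=True)
class TermMap:
    """A rule producing one RDF term from a database row."""

    kind: str  # constant | column | template
    value: str
    term_type: str = "iri"  # iri | literal | blank
    datatype: Optional[str] = None
    language: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "column", "template"):
            raise MappingValidationError(f"bad term map kind {self.kind!r}")
        if self.kind == "template" and not any(
            p[0] == "col" for p in parse_template(self.value)
        ):
            raise MappingValidationError(
                f"template {self.value!r} has no column placeholder"
            )
        if self.datatype is not None and self.term_type != "literal":
            raise MappingValidationError("datatype only allowed on literal term maps")


@dataclass(frozen=True)
class RefObjectMap:
    """Object generated as the subject of a parent triples map; the R2RML
    encoding of a foreign key, with explicit (child, parent) join columns."""

    parent_triples_map: str
    join_conditions: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        for child, parent in self.join_conditions:
            if not child or not parent:
                raise MappingValidationError("empty join condition column")


@dataclass(frozen=True)
class PredicateObjectMap:
    predicate_map: TermMap
    object_map: Union[TermMap, RefObjectMap]

    @property
    def is_ref(self) -> bool:
        return isinstance(self.object_map, RefObjectMap)


@dataclass
class TriplesMap:
    id: str
    logical_table: LogicalTable
    subject_map: TermMap
    predicate_object_maps: List[PredicateObjectMap] = field(default_factory=list)
    class_iris: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.subject_map.term_type == "literal":
            raise MappingValidationError(
                f"triples map {self.id}: subject map cannot be a literal"
            )

    @property
    def table(self) -> str:
        return self.logical_table.name_or_query


@dataclass
class MappingDocument:
    triples_maps: List[TriplesMap] = field(default_factory=list)
    base_iri: str = ""
    prefixes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [tm.id for tm in self.triples_maps]
        if len(ids) != len(set(ids)):
            raise MappingValidationError("duplicate triples map identifiers")
        for tm in self.triples_maps:
            for pom in tm.predicate_object_maps:
                if pom.is_ref:
                    parent = pom.object_map.parent_triples_map
                    if self.get(parent) is None:
                        raise MappingValidationError(
                            f"triples map {tm.id}: rr:parentTriplesMap "
                            f"{parent!r} does not resolve"
                        )

    def get(self, tm_id: str) -> Optional[TriplesMap]:
        for tm in self.triples_maps:
            if tm.id == tm_id:
                return tm
        return None

    def compact_iri(self, iri: str) -> str:
        """Render an IRI in prefixed form where a declared prefix applies.

        Used only for human-readable SQL output (projected predicate
        constants); falls back to the full IRI.
        """
        best = None
        for pfx, ns in self.prefixes.items():
            if iri.startswith(ns) and "/" not in iri[len(ns):] and "#" not in iri[len(ns):]:
                if best is None or len(ns) > len(self.prefixes[best]):
                    best = pfx
        if best is not None:
            return f"{best}:{iri[len(self.prefixes[best]):]}"
        return iri


# --------------------------------------------------------------------------
# parsing


def _one(g: Graph, s, p, tm_name: str, what: str):
    vals = list(g.objects(s, p))
    if len(vals) != 1:
        raise MappingValidationError(
            f"triples map {tm_name}: expected exactly one {what}, found {len(vals)}"
        )
    return vals[0]


def _parse_term_map(g: Graph, node, tm_name: str, default_type: str) -> TermMap:
    constant = next(iter(g.objects(node, RR.constant)), None)
    column = next(iter(g.objects(node, RR.column)), None)
    template = next(iter(g.objects(node, RR.template)), None)
    specified = [x for x in (constant, column, template) if x is not None]
    if len(specified) != 1:
        raise MappingValidationError(
            f"triples map {tm_name}: term map needs exactly one of "
            "rr:constant / rr:column / rr:template"
        )
    tt_node = next(iter(g.objects(node, RR.termType)), None)
    datatype = next(iter(g.objects(node, RR.datatype)), None)
    language = next(iter(g.objects(node, RR.language)), None)

    if constant is not None:
        kind, value = "constant", str(constant)
        term_type = "literal" if isinstance(constant, Literal) else "iri"
        if isinstance(constant, Literal):
            if constant.datatype is not None:
                datatype = constant.datatype
            if constant.language:
                language = Literal(constant.language)
    elif column is not None:
        kind, value = "column", str(column)
        term_type = default_type
    else:
        kind, value = "template", str(template)
        term_type = "iri"  # R2RML default for templates

    if tt_node is not None:
        term_type = {
            RR.IRI: "iri",
            RR.Literal: "literal",
            RR.BlankNode: "blank",
        }.get(tt_node, str(tt_node))
    if datatype is not None:
        term_type = "literal"
    return TermMap(
        kind=kind,
        value=value,
        term_type=term_type,
        datatype=str(datatype) if datatype is not None else None,
        language=str(language) if language is not None else None,
    )


def _local_id(node, graph: Graph) -> str:
    if isinstance(node, BNode):
        return f"_:{node}"
    s = str(node)
    for sep in ("#", "/"):
        if sep in s:
            tail = s.rsplit(sep, 1)[1]
            if tail:
                return tail
    return s


def parse_mapping(document: str, base_iri: str = "") -> MappingDocument:
    """Parse a Turtle R2RML document into a :class:`MappingDocument`.

    Both the shortcut properties (``rr:subject``, ``rr:predicate``,
    ``rr:object``, ``rr:tableName``) and the expanded map forms are
    accepted.  Unresolvable ``rr:parentTriplesMap`` references raise
    :class:`MappingValidationError`.
    """
    g = Graph()
    try:
        g.parse(data=document, format="turtle", publicID=base_iri or None)
    except Exception as exc:  # rdflib raises BadSyntax with line info
        raise MappingError(f"malformed Turtle: {exc}") from exc

    tm_nodes = sorted(set(g.subjects(RR.logicalTable, None)), key=str)
    maps: List[TriplesMap] = []
    node_ids = {node: _local_id(node, g) for node in tm_nodes}

    for node in tm_nodes:
        tm_id = node_ids[node]
        lt_node = _one(g, node, RR.logicalTable, tm_id, "rr:logicalTable")
        table_name = next(iter(g.objects(lt_node, RR.tableName)), None)
        sql_query = next(iter(g.objects(lt_node, RR.sqlQuery)), None)
        if table_name is not None:
            name = str(table_name)
            kind = "sql_view" if name.lower().startswith("v_") else "base_table"
            logical = LogicalTable(kind, name)
        elif sql_query is not None:
            logical = LogicalTable("sql_query", str(sql_query))
        else:
            raise MappingValidationError(
                f"triples map {tm_id}: logical table needs rr:tableName or rr:sqlQuery"
            )

        sm_node = next(iter(g.objects(node, RR.subjectMap)), None)
        subj_const = next(iter(g.objects(node, RR.subject)), None)
        if sm_node is not None:
            subject_map = _parse_term_map(g, sm_node, tm_id, default_type="iri")
            classes = tuple(sorted(str(c) for c in g.objects(sm_node, RR["class"])))
        elif subj_const is not None:
            subject_map = TermMap("constant", str(subj_const), "iri")
            classes = ()
        else:
            raise MappingValidationError(f"triples map {tm_id}: missing subject map")

        poms: List[PredicateObjectMap] = []
        for pom_node in g.objects(node, RR.predicateObjectMap):
            pred_node = next(iter(g.objects(pom_node, RR.predicateMap)), None)
            if pred_node is not None:
                pmap = _parse_term_map(g, pred_node, tm_id, default_type="iri")
            else:
                pconst = _one(g, pom_node, RR.predicate, tm_id, "predicate")
                pmap = TermMap("constant", str(pconst), "iri")

            om_node = next(iter(g.objects(pom_node, RR.objectMap)), None)
            oconst = next(iter(g.objects(pom_node, RR.object)), None)
            omap: Union[TermMap, RefObjectMap]
            if om_node is not None:
                parent = next(iter(g.objects(om_node, RR.parentTriplesMap)), None)
                if parent is not None:
                    joins = []
                    for jc in g.objects(om_node, RR.joinCondition):
                        child = _one(g, jc, RR.child, tm_id, "rr:child")
                        par = _one(g, jc, RR.parent, tm_id, "rr:parent")
                        joins.append((str(child), str(par)))
                    omap = RefObjectMap(
                        parent_triples_map=node_ids.get(parent, _local_id(parent, g)),
                        join_conditions=tuple(sorted(joins)),
                    )
                else:
                    omap = _parse_term_map(g, om_node, tm_id, default_type="literal")
            elif oconst is not None:
                if isinstance(oconst, Literal):
                    omap = TermMap(
                        "constant",
                        str(oconst),
                        "literal",
                        datatype=str(oconst.datatype) if oconst.datatype else None,
                        language=oconst.language,
                    )
                else:
                    omap = TermMap("constant", str(oconst), "iri")
            else:
                raise MappingValidationError(
                    f"triples map {tm_id}: predicate-object map without object"
                )
            poms.append(PredicateObjectMap(pmap, omap))

        # deterministic order: predicate IRI then object map repr
        poms.sort(key=lambda p: (p.predicate_map.value, repr(p.object_map)))
        maps.append(
            TriplesMap(
                id=tm_id,
                logical_table=logical,
                subject_map=subject_map,
                predicate_object_maps=poms,
                class_iris=classes,
            )
        )

    prefixes = {
        pfx: str(ns)
        for pfx, ns in g.namespaces()
        if pfx not in ("rr", "rdf", "rdfs", "xsd", "xml", "brick", "csvw", "dc",
                       "dcat", "dcmitype", "dcterms", "dcam", "doap", "foaf",
                       "geo", "odrl", "org", "owl", "prof", "prov", "qb",
                       "schema", "sh", "skos", "sosa", "ssn", "time", "vann",
                       "void", "wgs")
    }
    return MappingDocument(triples_maps=maps, base_iri=base_iri, prefixes=prefixes)


def serialize_mapping(doc: MappingDocument) -> str:
    """Re-serialize a mapping model to Turtle (inverse of parse, up to
    structural equality)."""
    g = Graph()
    g.bind("rr", RR)
    for pfx, ns in doc.prefixes.items():
        g.bind(pfx, Namespace(ns))
    base = Namespace(doc.base_iri or "http://rimql.invalid/map#")

    def tm_node(tm_id: str):
        return base[tm_id] if not tm_id.startswith("_:") else BNode(tm_id[2:])

    def emit_term_map(node, prop, tm: TermMap, classes: Sequence[str] = ()):
        m = BNode()
        g.add((node, prop, m))
        key = {"constant": RR.constant, "column": RR.column, "template": RR.template}[
            tm.kind
        ]
        if tm.kind == "constant" and tm.term_type == "iri":
            g.add((m, key, URIRef(tm.value)))
        elif tm.kind == "constant":
            g.add((m, key, Literal(tm.value, datatype=tm.datatype, lang=tm.language)))
        else:
            g.add((m, key, Literal(tm.value)))
        if tm.term_type == "literal" and tm.kind != "constant":
            g.add((m, RR.termType, RR.Literal))
            if tm.datatype:
                g.add((m, RR.datatype, URIRef(tm.datatype)))
            if tm.language:
                g.add((m, RR.language, Literal(tm.language)))
        elif tm.term_type == "blank":
            g.add((m, RR.termType, RR.BlankNode))
        for c in classes:
            g.add((m, RR["class"], URIRef(c)))

    for tm in doc.triples_maps:
        node = tm_node(tm.id)
        g.add((node, RDF.type, RR.TriplesMap))
        lt = BNode()
        g.add((node, RR.logicalTable, lt))
        if tm.logical_table.kind == "sql_query":
            g.add((lt, RR.sqlQuery, Literal(tm.logical_table.name_or_query)))
        else:
            g.add((lt, RR.tableName, Literal(tm.logical_table.name_or_query)))
        emit_term_map(node, RR.subjectMap, tm.subject_map, tm.class_iris)
        for pom in tm.predicate_object_maps:
            pnode = BNode()
            g.add((node, RR.predicateObjectMap, pnode))
            emit_term_map(pnode, RR.predicateMap, pom.predicate_map)
            if pom.is_ref:
                rom: RefObjectMap = pom.object_map  # type: ignore[assignment]
                onode = BNode()
                g.add((pnode, RR.objectMap, onode))
                g.add((onode, RR.parentTriplesMap, tm_node(rom.parent_triples_map)))
                for child, parent in rom.join_conditions:
                    jc = BNode()
                    g.add((onode, RR.joinCondition, jc))
                    g.add((jc, RR.child, Literal(child)))
                    g.add((jc, RR.parent, Literal(parent)))
            else:
                emit_term_map(pnode, RR.objectMap, pom.object_map)
    return g.serialize(format="turtle")


# --------------------------------------------------------------------------
# template algebra

_TEMPLATE_TOKEN = re.compile(r"\\[{}]|\{([^{}]+)\}|[^{}\\]+|\\")


def parse_template(template: str) -> List[Tuple[str, str]]:
    """Split a template into ``('lit', text)`` / ``('col', name)`` parts.

    ``\\{`` and ``\\}`` are literal braces, not placeholder delimiters.
    """
    parts: List[Tuple[str, str]] = []
    pos = 0
    for m in _TEMPLATE_TOKEN.finditer(template):
        if m.start() != pos:
            raise MappingValidationError(f"unbalanced braces in template {template!r}")
        pos = m.end()
        tok = m.group(0)
        if m.group(1) is not None:
            parts.append(("col", m.group(1)))
        else:
            text = tok[1] if tok.startswith("\\") and len(tok) == 2 else tok
            if parts and parts[-1][0] == "lit":
                parts[-1] = ("lit", parts[-1][1] + text)
            else:
                parts.append(("lit", text))
    if pos != len(template):
        raise MappingValidationError(f"unbalanced braces in template {template!r}")
    return parts


def referenced_columns(tm: Union[TermMap, RefObjectMap]) -> Tuple[str, ...]:
    """Columns a term map reads, in order of first appearance.

    Constants reference nothing; a column map references its single column;
    a template references each placeholder once.  For a
    :class:`RefObjectMap` these are the *child* join columns.
    """
    if isinstance(tm, RefObjectMap):
        return tuple(dict.fromkeys(c for c, _ in tm.join_conditions))
    if tm.kind == "constant":
        return ()
    if tm.kind == "column":
        return (tm.value,)
    cols = [name for kind, name in parse_template(tm.value) if kind == "col"]
    return tuple(dict.fromkeys(cols))


def lexical_form(value) -> str:
    """Canonical lexical form of a SQL value, shared by the materializer and
    the result mapper so both routes print identical literals."""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return f"{value:.1f}"
        return repr(value)
    return str(value)


def expand_template(tm: TermMap, row: Dict[str, object]):
    """Apply a term map to a row, returning an rdflib term or ``None``.

    ``None`` is returned when any referenced column is NULL (the R2RML NULL
    rule).  IRI templates percent-encode reserved characters inside the
    substituted fragments; the fixed template text is left untouched.
    """
    if tm.kind == "constant":
        if tm.term_type == "iri":
            return URIRef(tm.value)
        return Literal(tm.value, datatype=tm.datatype, lang=tm.language)

    cols = referenced_columns(tm)
    for c in cols:
        if c not in row:
            raise MappingError(f"row is missing referenced column {c!r}")
        if row[c] is None:
            return None

    if tm.kind == "column":
        lex = lexical_form(row[tm.value])
    else:
        out = []
        for kind, text in parse_template(tm.value):
            if kind == "lit":
                out.append(text)
            else:
                frag = lexical_form(row[text])
                if tm.term_type == "iri":
                    frag = urllib.parse.quote(frag, safe="")
                out.append(frag)
        lex = "".join(out)

    if tm.term_type == "iri":
        return URIRef(lex)
    if tm.term_type == "blank":
        return BNode(lex)
    return Literal(lex, datatype=tm.datatype, lang=tm.language)


def invert_template(tm: TermMap, term) -> Optional[Dict[str, str]]:
    """Recover column values from a term produced by a template map.

    Returns the unique assignment whose expansion reproduces ``term``, or
    ``None`` when the term does not fit the template skeleton.  Templates
    with two placeholders not separated by fixed text admit multiple
    decompositions and raise :class:`TemplateNotInvertibleError`; callers
    fall back to comparing against the expanded string expression.
    """
    if tm.kind != "template":
        raise MappingError("invert_template requires a template term map")
    parts = parse_template(tm.value)
    for a, b in zip(parts, parts[1:]):
        if a[0] == "col" and b[0] == "col":
            raise TemplateNotInvertibleError(
                f"template {tm.value!r} has adjacent placeholders"
            )
    pattern = []
    order: List[str] = []
    for kind, text in parts:
        if kind == "lit":
            pattern.append(re.escape(text))
        else:
            if text in order:
                pattern.append(f"(?P=c{order.index(text)})")
            else:
                pattern.append(f"(?P<c{len(order)}>.+?)")
                order.append(text)
    m = re.fullmatch("".join(pattern), str(term))
    if m is None:
        return None
    out: Dict[str, str] = {}
    for i, col in enumerate(order):
        frag = m.group(f"c{i}")
        if tm.term_type == "iri":
            frag = urllib.parse.unquote(frag)
        out[col] = frag
    return out
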