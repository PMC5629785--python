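"""SPARQL-to-SQL translation: the alpha/beta mappings, the name/genPRSQL/
genCondSQL generators, and the trans function over graph patterns.

The translation is compositional.  Every triple pattern becomes a scan of
the logical table(s) its predicate is mapped to, projecting the columns the
beta mapping associates with each variable position (renamed through the
name function) and filtering NULLs out of every referenced column.  AND
joins child queries on shared-variable alias equality, OPTIONAL becomes a
left outer join, UNION concatenates branches with NULL-padded aligned
projections, FILTER adds a WHERE condition over child aliases, and SELECT
projects the requested variables.

Queries are kept as a dialect-neutral AST (:class:`SqlQuery`) plus, per
union branch, the projection metadata (:class:`VarInfo`) linking each
output alias back to the R2RML term map that reconstructs the RDF term —
the database only ever sees and returns raw column values, so its indexes
stay usable, and the runtime re-assembles terms afterwards.
"""

from __future__ import annotations

import hashlib
import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .r2rml_mappings import (
    MappingDocument,
    PredicateObjectMap,
    RefObjectMap,
    TemplateNotInvertibleError,
    TermMap,
    TriplesMap,
    invert_template,
    parse_template,
    referenced_columns,
)
from .sparql_patterns import (
    ArithExpr,
    BoundExpr,
    Comparison,
    GraphPattern,
    InExpr,
    LogicalExpr,
    NotExpr,
    RDF_TYPE,
    Term,
    TriplePattern,
    UnsupportedConstructError,
    _generator_maps_for,
    required_triple_patterns,
)

__all__ = [
    "TranslationError",
    "Col",
    "Lit",
    "Concat",
    "BinOp",
    "NotNull",
    "Cmp",
    "InCond",
    "AndCond",
    "OrCond",
    "NotCond",
    "TrueCond",
    "FalseCond",
    "SelectItem",
    "FromItem",
    "LeftJoinItem",
    "SqlQuery",
    "VarInfo",
    "Branch",
    "TranslatedQuery",
    "TranslateFlags",
    "Translator",
    "alpha",
    "beta",
    "gen_name",
    "gen_pr_sql",
    "gen_cond_sql",
    "trans",
    "render_sql",
    "render_select_items",
    "render_condition",
]

_XSD = "http://www.w3.org/2001/XMLSchema#"
_NUMERIC_DATATYPES = {
    _XSD + t for t in ("integer", "decimal", "double", "float", "int", "long", "short")
}


class TranslationError(Exception):
    pass


# --------------------------------------------------------------------------
# SQL AST


@dataclass(frozen=True)
class Col:
    qualifier: Optional[str]
    column: str

    def __str__(self) -> str:
        return f"{self.qualifier}.{self.column}" if self.qualifier else self.column


@dataclass(frozen=True)
class Lit:
    value: object  # str | int | float | None


@dataclass(frozen=True)
class Concat:
    parts: Tuple[object, ...]  # Col | Lit


@dataclass(frozen=True)
class BinOp:
    op: str
    lhs: object
    rhs: object


SqlExpr = Union[Col, Lit, Concat, BinOp]


@dataclass(frozen=True)
class NotNull:
    expr: SqlExpr


@dataclass(frozen=True)
class IsNull:
    expr: SqlExpr


@dataclass(frozen=True)
class Cmp:
    op: str
    lhs: SqlExpr
    rhs: SqlExpr


@dataclass(frozen=True)
class InCond:
    expr: SqlExpr
    options: Tuple[Lit, ...]


@dataclass(frozen=True)
class AndCond:
    operands: Tuple[object, ...]


@dataclass(frozen=True)
class OrCond:
    operands: Tuple[object, ...]


@dataclass(frozen=True)
class NotCond:
    operand: object


class TrueCond:
    def __repr__(self) -> str:
        return "TrueCond"


class FalseCond:
    def __repr__(self) -> str:
        return "FalseCond"


TRUE = TrueCond()
FALSE = FalseCond()


@dataclass(frozen=True)
class SelectItem:
    expr: SqlExpr
    alias: str


@dataclass
class FromItem:
    relation: Union[str, "SqlQuery"]
    alias: Optional[str]


@dataclass
class LeftJoinItem:
    relation: Union[str, "SqlQuery"]
    alias: Optional[str]
    on: List[object]


@dataclass
class SqlQuery:
    """Dialect-neutral SELECT: projections, inner from-items (joined via
    WHERE equality conditions, so they can be freely reordered), left outer
    joins, and a conjunctive WHERE."""

    select_items: List[SelectItem] = field(default_factory=list)
    from_items: List[FromItem] = field(default_factory=list)
    left_joins: List[LeftJoinItem] = field(default_factory=list)
    where: List[object] = field(default_factory=list)
    distinct: bool = False

    def aliases(self) -> List[str]:
        return [s.alias for s in self.select_items]


# --------------------------------------------------------------------------
# projection metadata


@dataclass(frozen=True)
class VarInfo:
    """Links a SPARQL variable to the term map that rebuilds its RDF term
    and the output aliases carrying the referenced column values (empty for
    constant term maps).  ``indicator`` names a match-marker column used to
    decide boundness for constant-valued variables on optional sides."""

    term_map: TermMap
    aliases: Tuple[str, ...] = ()
    indicator: Optional[str] = None


@dataclass
class Branch:
    sql: SqlQuery
    vars: Dict[str, VarInfo]


@dataclass
class TranslatedQuery:
    """Translation result: one or more union branches, each with its own
    projection metadata, plus the projected variable list of the root
    SELECT (``None`` before the root is applied)."""

    branches: List[Branch]
    projected: Optional[List[str]] = None
    distinct: bool = False

    @property
    def is_empty(self) -> bool:
        return not self.branches


SRC_ALIAS = "__src"


# --------------------------------------------------------------------------
# name function


_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _local_name(iri_str: str) -> str:
    for sep in ("#", "/", ":"):
        if sep in iri_str:
            tail = iri_str.rsplit(sep, 1)[1]
            if tail:
                return tail
    return iri_str


class NameRegistry:
    """Generates the unique, deterministic aliases of the name function.
    Injective per query: distinct terms never share an alias."""

    def __init__(self) -> None:
        self._by_term: Dict[Tuple, str] = {}
        self._taken: Set[str] = set()

    def name(self, term: Term) -> str:
        key = term.key()
        if key in self._by_term:
            return self._by_term[key]
        if term.kind == "variable":
            base = "var_" + _SAFE.sub("_", term.lexical)
        elif term.kind == "iri":
            base = "iri_" + _SAFE.sub("_", _local_name(term.lexical))
        else:
            digest = hashlib.sha1(term.lexical.encode()).hexdigest()[:8]
            base = "lit_" + digest
        candidate, n = base, 1
        while candidate in self._taken:
            n += 1
            candidate = f"{base}_{n}"
        self._by_term[key] = candidate
        self._taken.add(candidate)
        return candidate


def gen_name(term: Term) -> str:
    """Alias for a single term (fresh registry; ?p -> var_p,
    :hasPatientName -> iri_hasPatientName)."""
    return NameRegistry().name(term)


def _column_aliases(base: str, n_cols: int) -> Tuple[str, ...]:
    if n_cols <= 1:
        return (base,)
    return tuple(f"{base}__{i}" for i in range(n_cols))


# --------------------------------------------------------------------------
# alpha / beta


def _predicate_poms(tm: TriplesMap, predicate_iri: str) -> List[PredicateObjectMap]:
    return [
        pom
        for pom in tm.predicate_object_maps
        if pom.predicate_map.kind == "constant"
        and pom.predicate_map.value == predicate_iri
    ]


def _subject_matches(tm: TriplesMap, subject: Term) -> bool:
    if subject.is_var:
        return True
    sm = tm.subject_map
    if sm.kind == "constant":
        return sm.value == subject.lexical
    if sm.kind == "column":
        return True
    try:
        return invert_template(sm, subject.lexical) is not None
    except TemplateNotInvertibleError:
        return True  # cannot decide statically; keep the map


def alpha(tp: TriplePattern, m: MappingDocument) -> List[TriplesMap]:
    """Triples maps (hence logical tables) a triple pattern can draw from.

    A constant predicate keeps the maps carrying a matching predicate map
    (``rdf:type`` matches via ``rr:class``); an unbound predicate keeps all
    maps; a constant subject further filters by subject-template match.
    """
    if tp.phantom:
        pinned = m.get(tp.pinned_map) if tp.pinned_map else None
        return [pinned] if pinned is not None else []
    out: List[TriplesMap] = []
    for tm in m.triples_maps:
        if not _subject_matches(tm, tp.subject):
            continue
        if tp.predicate.is_var:
            if tm.predicate_object_maps or tm.class_iris:
                out.append(tm)
        elif tp.predicate.lexical == RDF_TYPE:
            if tp.object.is_var:
                if tm.class_iris:
                    out.append(tm)
            elif tp.object.kind == "iri" and tp.object.lexical in tm.class_iris:
                out.append(tm)
        else:
            if _predicate_poms(tm, tp.predicate.lexical):
                out.append(tm)
    return out


def beta(
    tp: TriplePattern,
    position: str,
    m: MappingDocument,
    tm: Optional[TriplesMap] = None,
) -> Union[List[Col], str]:
    """Columns (or constant) associated with one position of a triple
    pattern under a chosen triples map.  Objects reached through a
    RefObjectMap resolve to the parent's subject columns."""
    if tm is None:
        matches = alpha(tp, m)
        if not matches:
            raise TranslationError(f"unmatchable triple pattern {tp}")
        tm = matches[0]
    table = tm.table
    if position == "subject":
        return [Col(table, c) for c in referenced_columns(tm.subject_map)]
    if position == "predicate":
        if tp.predicate.is_var:
            raise TranslationError("unbound predicate has no beta columns")
        if tp.predicate.lexical == RDF_TYPE:
            return f"'{m.compact_iri(tp.predicate.lexical)}'"
        return f"'{m.compact_iri(tp.predicate.lexical)}'"
    if position == "object":
        if tp.predicate.lexical == RDF_TYPE:
            return f"'{m.compact_iri(tp.object.lexical)}'" if not tp.object.is_var else []
        poms = _predicate_poms(tm, tp.predicate.lexical)
        if not poms:
            raise TranslationError(
                f"predicate {tp.predicate.lexical} is not mapped in {tm.id}"
            )
        om = poms[0].object_map
        if isinstance(om, RefObjectMap):
            parent = m.get(om.parent_triples_map)
            return [Col(parent.table, c) for c in referenced_columns(parent.subject_map)]
        if om.kind == "constant":
            return f"'{om.value}'"
        return [Col(table, c) for c in referenced_columns(om)]
    raise ValueError(f"bad position {position!r}")


# --------------------------------------------------------------------------
# genPRSQL / genCondSQL (worked-example form: single pattern, qualified)


def gen_pr_sql(
    tp: TriplePattern, m: MappingDocument, tm: Optional[TriplesMap] = None
) -> List[SelectItem]:
    """Projection list for one triple pattern: the beta columns of each
    position renamed through the name function; constant positions are
    projected as SQL string constants."""
    if tm is None:
        matches = alpha(tp, m)
        if not matches:
            return []
        tm = matches[0]
    names = NameRegistry()
    items: List[SelectItem] = []
    for position, term in (
        ("subject", tp.subject),
        ("predicate", tp.predicate),
        ("object", tp.object),
    ):
        alias = names.name(term)
        b = beta(tp, position, m, tm)
        if isinstance(b, str):
            items.append(SelectItem(Lit(b.strip("'")), alias))
        else:
            for col, a in zip(b, _column_aliases(alias, len(b))):
                items.append(SelectItem(col, a))
    return items


def gen_cond_sql(
    tp: TriplePattern, m: MappingDocument, tm: Optional[TriplesMap] = None
) -> object:
    """Match condition for one triple pattern: IS NOT NULL on every beta
    column, plus equality conditions for constant subject/object terms
    (constants inverted through templates where applicable)."""
    if tm is None:
        matches = alpha(tp, m)
        if not matches:
            return FALSE
        tm = matches[0]
    conds: List[object] = []
    seen: Set[Tuple] = set()

    def add(c: object) -> None:
        key = (type(c).__name__, repr(c))
        if key not in seen:
            seen.add(key)
            conds.append(c)

    for position, term in (("subject", tp.subject), ("object", tp.object)):
        b = beta(tp, position, m, tm)
        if isinstance(b, str):
            continue
        for col in b:
            add(NotNull(col))
        if not term.is_var and b:
            for c in _constant_eq_conditions(term, _position_term_map(tp, m, tm, position), b):
                add(c)
    if len(conds) == 1:
        return conds[0]
    return AndCond(tuple(conds)) if conds else TRUE


def _position_term_map(
    tp: TriplePattern, m: MappingDocument, tm: TriplesMap, position: str
) -> TermMap:
    if position == "subject":
        return tm.subject_map
    poms = _predicate_poms(tm, tp.predicate.lexical)
    om = poms[0].object_map
    if isinstance(om, RefObjectMap):
        return m.get(om.parent_triples_map).subject_map
    return om


def _literal_value(term: Term) -> object:
    if term.datatype in _NUMERIC_DATATYPES:
        try:
            if term.datatype == _XSD + "integer" or term.datatype == _XSD + "int":
                return int(term.lexical)
            return float(term.lexical)
        except ValueError:
            return term.lexical
    return term.lexical


def _constant_eq_conditions(
    term: Term, term_map: TermMap, cols: Sequence[Col]
) -> List[object]:
    """Equality conditions pinning a term map's columns to a constant term."""
    if term_map.kind == "constant":
        return [] if term_map.value == term.lexical else [FALSE]
    if (term_map.term_type == "iri") != (term.kind == "iri"):
        return [FALSE]
    if term_map.kind == "column":
        return [Cmp("=", cols[0], Lit(_literal_value(term)))]
    try:
        assignment = invert_template(term_map, term.lexical)
    except TemplateNotInvertibleError:
        # fall back to comparing against the expanded string expression
        expr = _expansion_expr(term_map, {c.column: c for c in cols})
        return [Cmp("=", expr, Lit(term.lexical))]
    if assignment is None:
        return [FALSE]
    by_name = {c.column: c for c in cols}
    order = referenced_columns(term_map)
    return [
        Cmp("=", by_name.get(col, cols[i]), Lit(assignment[col]))
        for i, col in enumerate(order)
    ]


def _expansion_expr(term_map: TermMap, cols_by_name: Dict[str, Col]) -> SqlExpr:
    """SQL string expression reproducing a term map's lexical expansion."""
    if term_map.kind == "column":
        return cols_by_name[term_map.value]
    parts: List[object] = []
    for kind, text in parse_template(term_map.value):
        if kind == "lit":
            parts.append(Lit(text))
        else:
            parts.append(cols_by_name[text])
    if len(parts) == 1:
        return parts[0]
    return Concat(tuple(parts))


def _info_expansion_expr(info: VarInfo, qualifier: Optional[str]) -> SqlExpr:
    """Expansion expression of a variable *through its projected aliases*."""
    tm = info.term_map
    if tm.kind == "constant":
        return Lit(tm.value)
    order = referenced_columns(tm)
    cols = {
        col: Col(qualifier, alias) for col, alias in zip(order, info.aliases)
    }
    return _expansion_expr(tm, cols)


def _skeletons_compatible(a: TermMap, b: TermMap) -> bool:
    """True when equal column values imply equal terms and vice versa, so a
    shared-variable join can compare raw columns instead of expansions."""
    if a.term_type != b.term_type and "iri" in (a.term_type, b.term_type):
        return False
    if a.kind == "column" and b.kind == "column":
        return True
    if a.kind == "template" and b.kind == "template":
        pa, pb = parse_template(a.value), parse_template(b.value)
        lits_a = [p for p in pa if p[0] == "lit"]
        lits_b = [p for p in pb if p[0] == "lit"]
        shape_a = [p[0] for p in pa]
        shape_b = [p[0] for p in pb]
        return shape_a == shape_b and lits_a == lits_b
    return False


# --------------------------------------------------------------------------
# flags


@dataclass(frozen=True)
class TranslateFlags:
    """Optimization toggles applied during translation.

    collapse_stg    self-join elimination for subject triple groups (O1)
    collapse_ostg   left-outer -> inner/scan rewriting for OSTGs (O2)
    reduce_union    dropping statically unsatisfiable union branches (O4)
    """

    collapse_stg: bool = False
    collapse_ostg: bool = False
    reduce_union: bool = False


# --------------------------------------------------------------------------
# the translator


class Translator:
    def __init__(
        self,
        mapping: MappingDocument,
        flags: TranslateFlags = TranslateFlags(),
        metadata=None,
    ) -> None:
        self.m = mapping
        self.flags = flags
        self.metadata = metadata
        self.names = NameRegistry()
        self._alias_n = 0
        self._ind_n = 0

    # -- helpers

    def _fresh_alias(self) -> str:
        self._alias_n += 1
        return f"t{self._alias_n}"

    def _fresh_indicator(self) -> str:
        self._ind_n += 1
        return f"__m{self._ind_n}"

    def _var_alias(self, name: str) -> str:
        return self.names.name(Term("variable", name))

    # -- public entry

    def translate(self, gp: GraphPattern) -> TranslatedQuery:
        if gp.kind == "TP":
            return self._translate_tp(gp.tp)
        if gp.kind == "AND":
            return self._translate_and(gp.children)
        if gp.kind == "OPT":
            return self._translate_opt(gp)
        if gp.kind == "UNION":
            branches: List[Branch] = []
            for c in gp.children:
                branches.extend(self.translate(c).branches)
            return TranslatedQuery(branches)
        if gp.kind == "FILTER":
            return self._translate_filter(gp)
        if gp.kind == "SELECT":
            return self._translate_select(gp)
        raise TranslationError(f"unknown pattern kind {gp.kind}")

    # -- triple patterns

    def _candidates(
        self, tp: TriplePattern
    ) -> List[Tuple[TriplesMap, Optional[PredicateObjectMap], Optional[str]]]:
        """(triples map, predicate-object map | None, class IRI | None)
        branches a triple pattern translates to."""
        out: List[Tuple[TriplesMap, Optional[PredicateObjectMap], Optional[str]]] = []
        if tp.phantom:
            if tp.pinned_map:
                tm = self.m.get(tp.pinned_map)
                if tm is not None:
                    out.append((tm, None, None))
            return out
        for tm in self.m.triples_maps:
            if not _subject_matches(tm, tp.subject):
                continue
            if tp.predicate.is_var:
                for cls in tm.class_iris:
                    out.append((tm, None, cls))
                for pom in tm.predicate_object_maps:
                    out.append((tm, pom, None))
            elif tp.predicate.lexical == RDF_TYPE:
                for cls in tm.class_iris:
                    if tp.object.is_var or (
                        tp.object.kind == "iri" and tp.object.lexical == cls
                    ):
                        out.append((tm, None, cls))
            else:
                for pom in _predicate_poms(tm, tp.predicate.lexical):
                    out.append((tm, pom, None))
        if self.flags.reduce_union and tp.predicate.is_var:
            out = [c for c in out if not self._branch_conflicts(tp, c)]
        return out

    @staticmethod
    def _branch_conflicts(
        tp: TriplePattern,
        cand: Tuple[TriplesMap, Optional[PredicateObjectMap], Optional[str]],
    ) -> bool:
        """Union reduction: the object term's kind/datatype contradicts the
        branch's object map, so its translation cannot produce answers."""
        tm, pom, cls = cand
        obj = tp.object
        if obj.is_var:
            return False
        if cls is not None:  # rdf:type branch: object is a class IRI
            return obj.kind != "iri" or obj.lexical != cls
        om = pom.object_map
        if isinstance(om, RefObjectMap):
            return obj.kind != "iri"
        if om.kind == "constant":
            return om.value != obj.lexical or (
                (om.term_type == "iri") != (obj.kind == "iri")
            )
        if (om.term_type == "iri") != (obj.kind == "iri"):
            return True
        if (
            obj.kind == "literal"
            and om.datatype is not None
            and obj.datatype is not None
            and om.datatype != obj.datatype
        ):
            return True
        return False

    def _translate_tp(self, tp: TriplePattern) -> TranslatedQuery:
        branches = []
        for cand in self._candidates(tp):
            builder = _ScanBuilder(self, cand[0])
            builder.add_tp(tp, cand[1], cand[2])
            branches.append(builder.build())
        return TranslatedQuery(branches)

    def translate_stg(
        self, tps: Sequence[TriplePattern], maps: Optional[Sequence[TriplesMap]] = None
    ) -> TranslatedQuery:
        """Translate a subject triple group without self-joins: one scan of
        the shared logical table projecting the union of the per-pattern
        projections under the conjunction of the per-pattern conditions."""
        if maps is None:
            maps = self._common_maps(tps)
        branches = []
        for tm in maps:
            builder = _ScanBuilder(self, tm)
            for tp in tps:
                cand = self._tp_cand_for_map(tp, tm)
                if cand is None:
                    builder = None
                    break
                builder.add_tp(tp, cand[0], cand[1])
            if builder is not None:
                branches.append(builder.build())
        return TranslatedQuery(branches)

    def _tp_cand_for_map(
        self, tp: TriplePattern, tm: TriplesMap
    ) -> Optional[Tuple[Optional[PredicateObjectMap], Optional[str]]]:
        for cand_tm, pom, cls in self._candidates(tp):
            if cand_tm.id == tm.id:
                return (pom, cls)
        return None

    def _common_maps(self, tps: Sequence[TriplePattern]) -> List[TriplesMap]:
        sets = []
        for tp in tps:
            sets.append({tm.id for tm, _, _ in self._candidates(tp)})
        common = set.intersection(*sets) if sets else set()
        return [tm for tm in self.m.triples_maps if tm.id in common]

    # -- AND

    def _resolve_phantoms(self, children: List[GraphPattern]) -> List[GraphPattern]:
        req = []
        for c in children:
            req.extend(required_triple_patterns(c))
        out = []
        for c in children:
            if c.kind == "TP" and c.tp.phantom and c.tp.pinned_map is None:
                candidates = _generator_maps_for(c.tp.subject, req, self.m)
                if len(candidates) != 1:
                    continue  # unresolvable phantom contributes nothing; drop
                out.append(GraphPattern.TP(replace(c.tp, pinned_map=candidates[0])))
            else:
                out.append(c)
        return out

    def _and_units(self, children: List[GraphPattern]) -> List[TranslatedQuery]:
        children = self._resolve_phantoms(children)
        units: List[TranslatedQuery] = []
        i = 0
        while i < len(children):
            c = children[i]
            if self.flags.collapse_stg and c.kind == "TP":
                run = [c.tp]
                j = i + 1
                while (
                    j < len(children)
                    and children[j].kind == "TP"
                    and children[j].tp.subject.key() == c.tp.subject.key()
                ):
                    run.append(children[j].tp)
                    j += 1
                if len(run) >= 2:
                    common = self._common_maps(run)
                    if common:
                        units.append(self.translate_stg(run, common))
                        i = j
                        continue
            units.append(self.translate(c))
            i += 1
        return units

    def _translate_and(self, children: List[GraphPattern]) -> TranslatedQuery:
        units = self._and_units(children)
        if len(units) == 1:
            return units[0]
        if any(u.is_empty for u in units):
            return TranslatedQuery([])
        branches = []
        for combo in itertools.product(*[u.branches for u in units]):
            branches.append(self._compose_inner(list(combo)))
        return TranslatedQuery(branches)

    def _join_conditions(
        self,
        a: VarInfo,
        qa: Optional[str],
        b: VarInfo,
        qb: Optional[str],
    ) -> List[object]:
        ta, tb = a.term_map, b.term_map
        if ta.kind == "constant" and tb.kind == "constant":
            return [] if ta.value == tb.value else [FALSE]
        if ta.kind == "constant":
            return self._join_conditions(b, qb, a, qa)
        if tb.kind == "constant":
            term = Term(
                "iri" if tb.term_type == "iri" else "literal",
                tb.value,
                datatype=tb.datatype,
            )
            cols = [Col(qa, al) for al in a.aliases]
            order = referenced_columns(ta)
            by_name = dict(zip(order, cols))
            if ta.kind == "column":
                return _constant_eq_conditions(term, ta, cols)
            try:
                assignment = invert_template(ta, term.lexical)
            except TemplateNotInvertibleError:
                return [Cmp("=", _info_expansion_expr(a, qa), Lit(term.lexical))]
            if assignment is None:
                return [FALSE]
            return [
                Cmp("=", by_name[c], Lit(assignment[c])) for c in order
            ]
        if _skeletons_compatible(ta, tb):
            return [
                Cmp("=", Col(qa, x), Col(qb, y))
                for x, y in zip(a.aliases, b.aliases)
            ]
        if "iri" in (ta.term_type, tb.term_type) and ta.term_type != tb.term_type:
            return [FALSE]
        return [
            Cmp("=", _info_expansion_expr(a, qa), _info_expansion_expr(b, qb))
        ]

    def _compose_inner(self, branches: List[Branch]) -> Branch:
        if len(branches) == 1:
            return branches[0]
        q = SqlQuery()
        vars_out: Dict[str, VarInfo] = {}
        owner: Dict[str, Tuple[VarInfo, str]] = {}
        projected_aux: Set[str] = set()
        for b in branches:
            alias = self._fresh_alias()
            q.from_items.append(FromItem(b.sql, alias))
            for v, info in b.vars.items():
                if v in owner:
                    prev, palias = owner[v]
                    q.where.extend(self._join_conditions(prev, palias, info, alias))
                    continue
                owner[v] = (info, alias)
                for a in info.aliases:
                    q.select_items.append(SelectItem(Col(alias, a), a))
                if info.indicator and info.indicator not in projected_aux:
                    q.select_items.append(
                        SelectItem(Col(alias, info.indicator), info.indicator)
                    )
                    projected_aux.add(info.indicator)
                vars_out[v] = info
        return Branch(q, vars_out)

    # -- OPTIONAL

    def _translate_opt(self, node: GraphPattern) -> TranslatedQuery:
        if self.flags.collapse_ostg:
            collapsed = self._try_collapse_ostg(node)
            if collapsed is not None:
                return collapsed
        left, right = node.children
        ltq = self.translate(left)
        rtq = self.translate(right)
        return self._compose_left_join(ltq, rtq)

    def _compose_left_join(
        self, ltq: TranslatedQuery, rtq: TranslatedQuery, drop_object_notnull: bool = False
    ) -> TranslatedQuery:
        if ltq.is_empty:
            return TranslatedQuery([])
        if rtq.is_empty:
            return ltq
        if len(rtq.branches) != 1:
            raise UnsupportedConstructError(
                "OPTIONAL over a union pattern is not supported"
            )
        rb = rtq.branches[0]
        needs_indicator = any(
            info.term_map.kind == "constant" and v not in b.vars
            for b in ltq.branches
            for v, info in rb.vars.items()
        )
        indicator = None
        if needs_indicator:
            indicator = self._fresh_indicator()
            rb.sql.select_items.append(SelectItem(Lit(1), indicator))
        out = []
        for lb in ltq.branches:
            la = self._fresh_alias()
            ra = self._fresh_alias()
            q = SqlQuery(from_items=[FromItem(lb.sql, la)])
            on: List[object] = []
            vars_out: Dict[str, VarInfo] = {}
            for v, info in lb.vars.items():
                for a in info.aliases:
                    q.select_items.append(SelectItem(Col(la, a), a))
                if info.indicator:
                    q.select_items.append(
                        SelectItem(Col(la, info.indicator), info.indicator)
                    )
                vars_out[v] = info
            for v, info in rb.vars.items():
                if v in lb.vars:
                    on.extend(self._join_conditions(lb.vars[v], la, info, ra))
                    continue
                for a in info.aliases:
                    q.select_items.append(SelectItem(Col(ra, a), a))
                if info.term_map.kind == "constant":
                    info = replace(info, indicator=indicator)
                    if indicator:
                        q.select_items.append(
                            SelectItem(Col(ra, indicator), indicator)
                        )
                elif info.indicator:
                    q.select_items.append(
                        SelectItem(Col(ra, info.indicator), info.indicator)
                    )
                vars_out[v] = info
            q.left_joins.append(LeftJoinItem(rb.sql, ra, on))
            out.append(Branch(q, vars_out))
        return TranslatedQuery(out)

    def _try_collapse_ostg(self, node: GraphPattern) -> Optional[TranslatedQuery]:
        """Rewrite an OPT chain whose optional sides are single triple
        patterns anchored by a same-subject run of required patterns over
        the same logical table: the left outer join becomes an inner join
        (a single scan when self-join elimination is also on) and the
        optional objects lose their IS NOT NULL, so NULL columns surface as
        unbound variables.  Optionals that do not qualify stay left joins.
        """
        chain: List[TriplePattern] = []
        cur = node
        while (
            cur.kind == "OPT"
            and cur.children[1].kind == "TP"
            and cur.children[1].tp.object.is_var
            and not cur.children[1].tp.predicate.is_var
        ):
            chain.append(cur.children[1].tp)
            cur = cur.children[0]
        if not chain:
            return None
        chain.reverse()
        base = cur
        if base.kind == "TP":
            base_children: List[GraphPattern] = [base]
        elif base.kind == "AND":
            base_children = self._resolve_phantoms(base.children)
        else:
            return None

        # maximal consecutive TP runs of the required side, by subject
        runs: List[Tuple[Tuple, List[TriplePattern], int]] = []
        i = 0
        while i < len(base_children):
            c = base_children[i]
            if c.kind != "TP":
                i += 1
                continue
            key = c.tp.subject.key()
            run = [c.tp]
            j = i + 1
            while (
                j < len(base_children)
                and base_children[j].kind == "TP"
                and base_children[j].tp.subject.key() == key
            ):
                run.append(base_children[j].tp)
                j += 1
            runs.append((key, run, i))
            i = j
        anchor_by_subject: Dict[Tuple, Tuple[Tuple, List[TriplePattern], int]] = {}
        for r in runs:
            prev = anchor_by_subject.get(r[0])
            if prev is None or len(r[1]) >= len(prev[1]):
                anchor_by_subject[r[0]] = r

        # variable occurrence counts for freshness of optional objects
        var_count: Dict[str, int] = {}
        for c in base_children:
            for v in (
                {t.lexical for t in c.tp.variables()}
                if c.kind == "TP"
                else c.variables()
            ):
                var_count[v] = var_count.get(v, 0) + 1
        for tp in chain:
            for t in tp.variables():
                var_count[t.lexical] = var_count.get(t.lexical, 0) + 1

        group_opts: Dict[int, List[TriplePattern]] = {}
        group_maps: Dict[int, List[TriplesMap]] = {}
        rest: List[TriplePattern] = []
        for tp in chain:
            run = anchor_by_subject.get(tp.subject.key())
            ok = False
            if run is not None and tp.object.is_var and var_count.get(
                tp.object.lexical, 0
            ) == 1:
                maps = group_maps.get(run[2])
                if maps is None:
                    maps = self._common_maps(run[1])
                    group_maps[run[2]] = maps
                ok = bool(maps) and self._same_table_pom(tp, maps)
            if ok:
                group_opts.setdefault(run[2], []).append(tp)
            else:
                rest.append(tp)
        if not group_opts:
            return None

        grouped_indices: Set[int] = set()
        for start in group_opts:
            run = next(r for r in runs if r[2] == start)
            grouped_indices.update(range(start, start + len(run[1])))

        units: List[TranslatedQuery] = []
        leftovers: List[GraphPattern] = []

        def flush() -> None:
            if leftovers:
                units.extend(self._and_units(list(leftovers)))
                leftovers.clear()

        idx = 0
        while idx < len(base_children):
            if idx in grouped_indices and any(r[2] == idx for r in runs):
                run = next(r for r in runs if r[2] == idx)
                flush()
                units.append(
                    self._collapse_group(
                        run[1], group_opts[run[2]], group_maps[run[2]]
                    )
                )
                idx += len(run[1])
            else:
                leftovers.append(base_children[idx])
                idx += 1
        flush()

        if any(u.is_empty for u in units):
            result = TranslatedQuery([])
        elif len(units) == 1:
            result = units[0]
        else:
            result = TranslatedQuery(
                [
                    self._compose_inner(list(combo))
                    for combo in itertools.product(*[u.branches for u in units])
                ]
            )
        for tp in rest:
            result = self._compose_left_join(result, self._translate_tp(tp))
        return result

    def _collapse_group(
        self,
        anchor: List[TriplePattern],
        opts: List[TriplePattern],
        maps: List[TriplesMap],
    ) -> TranslatedQuery:
        if self.flags.collapse_stg:
            branches = []
            for tm in maps:
                builder = _ScanBuilder(self, tm)
                for tp in anchor:
                    cand = self._tp_cand_for_map(tp, tm)
                    builder.add_tp(tp, cand[0], cand[1])
                for tp in opts:
                    cand = self._tp_cand_for_map(tp, tm)
                    builder.add_tp(tp, cand[0], cand[1], optional=True)
                branches.append(builder.build())
            return TranslatedQuery(branches)
        # inner-join form: anchor patterns translated individually, each
        # optional pattern an extra scan without the object IS NOT NULL
        units = [self._translate_tp(tp) for tp in anchor]
        for tp in opts:
            brs = []
            for tm in maps:
                cand = self._tp_cand_for_map(tp, tm)
                builder = _ScanBuilder(self, tm)
                builder.add_tp(tp, cand[0], cand[1], optional=True)
                brs.append(builder.build())
            units.append(TranslatedQuery(brs))
        return TranslatedQuery(
            [
                self._compose_inner(list(combo))
                for combo in itertools.product(*[u.branches for u in units])
            ]
        )

    def _same_table_pom(
        self, tp: TriplePattern, maps: Sequence[TriplesMap]
    ) -> bool:
        """The optional pattern's object must live in the anchor's own
        logical table (a plain column/template map, not a ref-object join)
        under every candidate anchor map."""
        if tp.predicate.is_var or tp.predicate.lexical == RDF_TYPE:
            return False
        for tm in maps:
            poms = _predicate_poms(tm, tp.predicate.lexical)
            if len(poms) != 1 or poms[0].is_ref:
                return False
        return True

    # -- FILTER / SELECT

    def _wrap(self, b: Branch) -> Tuple[Branch, str]:
        alias = self._fresh_alias()
        q = SqlQuery(from_items=[FromItem(b.sql, alias)])
        done: Set[str] = set()
        for v, info in b.vars.items():
            for a in info.aliases:
                if a not in done:
                    q.select_items.append(SelectItem(Col(alias, a), a))
                    done.add(a)
            if info.indicator and info.indicator not in done:
                q.select_items.append(SelectItem(Col(alias, info.indicator), info.indicator))
                done.add(info.indicator)
        return Branch(q, dict(b.vars)), alias

    def _translate_filter(self, node: GraphPattern) -> TranslatedQuery:
        child = self.translate(node.children[0])
        out = []
        for b in child.branches:
            wrapped, alias = self._wrap(b)
            cond = _FilterCompiler(self, b.vars, alias).compile(node.filter_expr)
            wrapped.sql.where.append(cond)
            out.append(wrapped)
        return TranslatedQuery(out, child.projected, child.distinct)

    def _translate_select(self, node: GraphPattern) -> TranslatedQuery:
        child = self.translate(node.children[0])
        projected = node.projected_vars or []
        out = []
        for b in child.branches:
            alias = self._fresh_alias()
            q = SqlQuery(
                from_items=[FromItem(b.sql, alias)], distinct=node.distinct
            )
            vars_out: Dict[str, VarInfo] = {}
            done: Set[str] = set()
            for v in projected:
                info = b.vars.get(v)
                if info is None:
                    continue
                for a in info.aliases:
                    if a not in done:
                        q.select_items.append(SelectItem(Col(alias, a), a))
                        done.add(a)
                if info.indicator and info.indicator not in done:
                    q.select_items.append(
                        SelectItem(Col(alias, info.indicator), info.indicator)
                    )
                    done.add(info.indicator)
                vars_out[v] = info
            if not q.select_items:
                q.select_items.append(SelectItem(Lit(1), "__one"))
            out.append(Branch(q, vars_out))
        return TranslatedQuery(out, list(projected), node.distinct)


class _UnboundVariable(Exception):
    pass


class _FilterCompiler:
    """Compiles a SPARQL filter expression to a SQL condition over the
    aliases of one branch.  A comparison over an unbound variable is a
    SPARQL type error, which eliminates the row: it compiles to FALSE."""

    def __init__(self, tr: Translator, vars: Dict[str, VarInfo], qualifier: str) -> None:
        self.tr = tr
        self.vars = vars
        self.q = qualifier

    def compile(self, expr) -> object:
        if isinstance(expr, LogicalExpr):
            ops = tuple(self.compile(o) for o in expr.operands)
            return AndCond(ops) if expr.op == "and" else OrCond(ops)
        if isinstance(expr, NotExpr):
            return NotCond(self.compile(expr.operand))
        if isinstance(expr, BoundExpr):
            info = self.vars.get(expr.variable.lexical)
            if info is None:
                return FALSE
            if info.term_map.kind == "constant":
                if info.indicator:
                    return NotNull(Col(self.q, info.indicator))
                return TRUE
            return AndCond(tuple(NotNull(Col(self.q, a)) for a in info.aliases))
        if isinstance(expr, InExpr):
            try:
                lhs = self.value(expr.lhs)
            except _UnboundVariable:
                return FALSE
            cond = InCond(lhs, tuple(Lit(_literal_value(t)) for t in expr.options))
            return NotCond(cond) if expr.negated else cond
        if isinstance(expr, Comparison):
            if expr.op in ("=", "!="):
                special = self._term_equality(expr)
                if special is not None:
                    return special
            try:
                return Cmp(expr.op, self.value(expr.lhs), self.value(expr.rhs))
            except _UnboundVariable:
                return FALSE
        if isinstance(expr, Term):
            # bare variable/literal used as an effective boolean value
            try:
                v = self.value(expr)
            except _UnboundVariable:
                return FALSE
            return Cmp("!=", v, Lit(0))
        raise TranslationError(f"unsupported filter operator {expr!r}")

    def _term_equality(self, expr: Comparison):
        sides = [expr.lhs, expr.rhs]
        if not all(isinstance(s, Term) for s in sides):
            return None
        terms: List[Term] = sides  # type: ignore[assignment]
        var_side = next((t for t in terms if t.is_var), None)
        iri_side = next((t for t in terms if t.kind == "iri"), None)
        if var_side is None or iri_side is None:
            return None
        info = self.vars.get(var_side.lexical)
        if info is None:
            return FALSE
        conds = self.tr._join_conditions(
            info,
            self.q,
            VarInfo(TermMap("constant", iri_side.lexical, "iri")),
            None,
        )
        cond = conds[0] if len(conds) == 1 else AndCond(tuple(conds)) if conds else TRUE
        return NotCond(cond) if expr.op == "!=" else cond

    def value(self, node) -> SqlExpr:
        if isinstance(node, Term):
            if node.is_var:
                info = self.vars.get(node.lexical)
                if info is None:
                    raise _UnboundVariable(node.lexical)
                return _info_expansion_expr(info, self.q)
            if node.kind == "iri":
                return Lit(node.lexical)
            return Lit(_literal_value(node))
        if isinstance(node, ArithExpr):
            return BinOp(node.op, self.value(node.lhs), self.value(node.rhs))
        raise TranslationError(f"unsupported value expression {node!r}")


# --------------------------------------------------------------------------
# single-scan builder


class _ScanBuilder:
    """Accumulates projections and conditions of one or more triple
    patterns over a single scan of one triples map's logical table (the
    trans-stg shape).  Ref-object-map objects pull in their parent table as
    additional inner from-items."""

    def __init__(self, tr: Translator, tm: TriplesMap) -> None:
        self.tr = tr
        self.tm = tm
        self.q = SqlQuery(from_items=[FromItem(tm.table, None)])
        self.vars: Dict[str, VarInfo] = {}
        # first binding site of each variable: (term map, raw columns, qualifier)
        self._var_site: Dict[str, Tuple[TermMap, Tuple[str, ...], Optional[str]]] = {}
        self._cond_keys: Set[str] = set()
        self._item_keys: Set[str] = set()
        self._parent_n = 0
        self._base_qualifier: Optional[str] = None

    def _qualify(self) -> Optional[str]:
        """Base-table qualifier; needed once parent joins are present."""
        if self._parent_n and self._base_qualifier is None:
            self._base_qualifier = "c"
            self.q.from_items[0].alias = "c"

            def requalify(expr):
                if isinstance(expr, Col) and expr.qualifier is None:
                    return Col("c", expr.column)
                if isinstance(expr, Concat):
                    return Concat(tuple(requalify(p) for p in expr.parts))
                if isinstance(expr, BinOp):
                    return BinOp(expr.op, requalify(expr.lhs), requalify(expr.rhs))
                return expr

            def requalify_cond(c):
                if isinstance(c, NotNull):
                    return NotNull(requalify(c.expr))
                if isinstance(c, Cmp):
                    return Cmp(c.op, requalify(c.lhs), requalify(c.rhs))
                return c

            self.q.select_items = [
                SelectItem(requalify(s.expr), s.alias) for s in self.q.select_items
            ]
            self.q.where = [requalify_cond(c) for c in self.q.where]
            self._var_site = {
                k: (tm, cols, "c" if q is None else q)
                for k, (tm, cols, q) in self._var_site.items()
            }
        return self._base_qualifier

    def _add_cond(self, cond: object) -> None:
        key = repr(cond)
        if key not in self._cond_keys:
            self._cond_keys.add(key)
            self.q.where.append(cond)

    def _add_item(self, item: SelectItem) -> None:
        if item.alias not in self._item_keys:
            self._item_keys.add(item.alias)
            self.q.select_items.append(item)

    def _project_var(
        self,
        name: str,
        term_map: TermMap,
        qualifier: Optional[str],
        not_null: bool = True,
    ) -> None:
        cols = referenced_columns(term_map)
        if not_null:
            for c in cols:
                self._add_cond(NotNull(Col(qualifier, c)))
        if name in self._var_site:
            prev_tm, prev_cols, prev_q = self._var_site[name]
            if prev_tm == term_map and prev_cols == cols and prev_q == qualifier:
                return  # same binding site; nothing to add
            a = VarInfo(prev_tm, prev_cols)  # aliases stand in for raw columns
            b = VarInfo(term_map, tuple(cols))
            for cond in self.tr._join_conditions(a, prev_q, b, qualifier):
                self._add_cond(cond)
            return
        self._var_site[name] = (term_map, tuple(cols), qualifier)
        base = self.tr._var_alias(name)
        aliases = _column_aliases(base, len(cols)) if cols else ()
        for col, a in zip(cols, aliases):
            self._add_item(SelectItem(Col(qualifier, col), a))
        self.vars[name] = VarInfo(term_map, aliases)

    def _constrain_constant(
        self,
        term: Term,
        term_map: TermMap,
        qualifier: Optional[str],
        not_null: bool = True,
    ) -> None:
        cols = [Col(qualifier, c) for c in referenced_columns(term_map)]
        if not_null:
            for c in cols:
                self._add_cond(NotNull(c))
        for cond in _constant_eq_conditions(term, term_map, cols):
            self._add_cond(cond)

    def add_tp(
        self,
        tp: TriplePattern,
        pom: Optional[PredicateObjectMap],
        class_iri: Optional[str],
        optional: bool = False,
    ) -> None:
        tm = self.tm
        base_q = self._base_qualifier
        # subject
        if tp.subject.is_var:
            self._project_var(tp.subject.lexical, tm.subject_map, base_q)
        else:
            self._constrain_constant(tp.subject, tm.subject_map, base_q)
        # predicate variable binds to the branch's constant predicate
        if tp.predicate.is_var:
            pred_iri = RDF_TYPE if class_iri is not None else pom.predicate_map.value
            if tp.predicate.lexical not in self.vars:
                self.vars[tp.predicate.lexical] = VarInfo(
                    TermMap("constant", pred_iri, "iri")
                )
        if tp.phantom:
            return
        # object
        if class_iri is not None:
            if tp.object.is_var:
                if tp.object.lexical not in self.vars:
                    self.vars[tp.object.lexical] = VarInfo(
                        TermMap("constant", class_iri, "iri")
                    )
            elif not (tp.object.kind == "iri" and tp.object.lexical == class_iri):
                self._add_cond(FALSE)
            return
        om = pom.object_map
        if isinstance(om, RefObjectMap):
            parent = self.tr.m.get(om.parent_triples_map)
            self._parent_n += 1
            palias = f"p{self._parent_n}"
            base_q = self._qualify()
            self.q.from_items.append(FromItem(parent.table, palias))
            for child_col, parent_col in om.join_conditions:
                self._add_cond(
                    Cmp("=", Col(base_q, child_col), Col(palias, parent_col))
                )
            if tp.object.is_var:
                self._project_var(
                    tp.object.lexical, parent.subject_map, palias, not_null=not optional
                )
            else:
                self._constrain_constant(tp.object, parent.subject_map, palias)
        else:
            if tp.object.is_var:
                self._project_var(
                    tp.object.lexical, om, base_q, not_null=not optional
                )
            else:
                self._constrain_constant(tp.object, om, base_q)

    def build(self) -> Branch:
        return Branch(self.q, self.vars)


# --------------------------------------------------------------------------
# module-level trans


def trans(gp: GraphPattern, m: MappingDocument, flags: TranslateFlags = TranslateFlags()) -> TranslatedQuery:
    """Translate a graph pattern under a mapping document into a SQL query
    whose evaluation returns the rows encoding the pattern's solutions."""
    return Translator(m, flags).translate(gp)


# --------------------------------------------------------------------------
# rendering


_BARE_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*$")
_SQL_KEYWORDS = {
    "select", "from", "where", "join", "on", "union", "group", "order",
    "table", "procedure", "value", "values", "left", "inner", "outer", "as",
}


def _quote_ident(name: str, dialect: str) -> str:
    if dialect == "mysql":
        return f"`{name}`"
    if dialect == "sqlite":
        return f'"{name}"'
    if _BARE_IDENT.fullmatch(name) and name.lower() not in _SQL_KEYWORDS:
        return name
    return f'"{name}"'


def _render_expr(e: SqlExpr, dialect: str) -> str:
    if isinstance(e, Col):
        col = _quote_ident(e.column, dialect)
        if e.qualifier:
            return f"{_quote_ident(e.qualifier, dialect)}.{col}"
        return col
    if isinstance(e, Lit):
        v = e.value
        if v is None:
            return "NULL"
        if isinstance(v, bool):
            return "1" if v else "0"
        if isinstance(v, (int, float)):
            return repr(v)
        s = str(v).replace("'", "''")
        return f"'{s}'"
    if isinstance(e, Concat):
        parts = [_render_expr(p, dialect) for p in e.parts]
        if dialect == "mysql":
            return "CONCAT(" + ", ".join(parts) + ")"
        return "(" + " || ".join(parts) + ")"
    if isinstance(e, BinOp):
        return (
            "("
            + _render_expr(e.lhs, dialect)
            + f" {e.op} "
            + _render_expr(e.rhs, dialect)
            + ")"
        )
    raise TranslationError(f"cannot render expression {e!r}")


def render_condition(c: object, dialect: str = "generic") -> str:
    if isinstance(c, TrueCond):
        return "1=1"
    if isinstance(c, FalseCond):
        return "1=0"
    if isinstance(c, NotNull):
        return f"{_render_expr(c.expr, dialect)} IS NOT NULL"
    if isinstance(c, IsNull):
        return f"{_render_expr(c.expr, dialect)} IS NULL"
    if isinstance(c, Cmp):
        op = "<>" if c.op == "!=" else c.op
        return f"{_render_expr(c.lhs, dialect)} {op} {_render_expr(c.rhs, dialect)}"
    if isinstance(c, InCond):
        opts = ", ".join(_render_expr(o, dialect) for o in c.options)
        return f"{_render_expr(c.expr, dialect)} IN ({opts})"
    if isinstance(c, AndCond):
        if not c.operands:
            return "1=1"
        return "(" + " AND ".join(render_condition(o, dialect) for o in c.operands) + ")"
    if isinstance(c, OrCond):
        return "(" + " OR ".join(render_condition(o, dialect) for o in c.operands) + ")"
    if isinstance(c, NotCond):
        return f"NOT ({render_condition(c.operand, dialect)})"
    raise TranslationError(f"cannot render condition {c!r}")


def render_select_items(items: Sequence[SelectItem], dialect: str = "generic") -> str:
    return ", ".join(
        f"{_render_expr(i.expr, dialect)} AS {_quote_ident(i.alias, dialect)}"
        for i in items
    )


def _render_query(q: SqlQuery, dialect: str) -> str:
    head = "SELECT DISTINCT " if q.distinct else "SELECT "
    if q.select_items:
        head += render_select_items(q.select_items, dialect)
    else:
        head += "1 AS __one"
    # sqlite's query flattener merges derived tables into the enclosing
    # join, whose width is capped at 64 relations; a LIMIT clause keeps each
    # derived table a single relation
    barrier = " LIMIT -1" if dialect == "sqlite" else ""
    parts = [head]
    if q.from_items:
        rels = []
        for f in q.from_items:
            if isinstance(f.relation, SqlQuery):
                rel = "(" + _render_query(f.relation, dialect) + barrier + ")"
            else:
                rel = _quote_ident(f.relation, dialect)
            if f.alias:
                rel += f" AS {_quote_ident(f.alias, dialect)}"
            rels.append(rel)
        parts.append("FROM " + ", ".join(rels))
    for lj in q.left_joins:
        if isinstance(lj.relation, SqlQuery):
            rel = "(" + _render_query(lj.relation, dialect) + barrier + ")"
        else:
            rel = _quote_ident(lj.relation, dialect)
        if lj.alias:
            rel += f" AS {_quote_ident(lj.alias, dialect)}"
        on = (
            " AND ".join(render_condition(c, dialect) for c in lj.on)
            if lj.on
            else "1=1"
        )
        parts.append(f"LEFT OUTER JOIN {rel} ON {on}")
    if q.where:
        parts.append(
            "WHERE " + " AND ".join(render_condition(c, dialect) for c in q.where)
        )
    return " ".join(parts)


def render_sql(q: Union[SqlQuery, TranslatedQuery], dialect: str = "generic") -> str:
    """Deterministic SQL text for a query AST.  Union branches are aligned
    on the lexicographically ordered union of their aliases, padded with
    NULLs, and tagged with a ``__src`` branch discriminator."""
    if isinstance(q, SqlQuery):
        return _render_query(q, dialect)
    if not q.branches:
        return "SELECT NULL AS __none WHERE 1=0"
    if len(q.branches) == 1:
        return _render_query(q.branches[0].sql, dialect)
    all_aliases = sorted({a for b in q.branches for a in b.sql.aliases()})
    rendered = []
    for i, b in enumerate(q.branches):
        have = set(b.sql.aliases())
        cols = []
        for a in all_aliases:
            qa = _quote_ident(a, dialect)
            cols.append(f"u.{qa}" if a in have else f"NULL AS {qa}")
        cols.append(f"{i} AS {_quote_ident(SRC_ALIAS, dialect)}")
        rendered.append(
            "SELECT "
            + ", ".join(cols)
            + " FROM ("
            + _render_query(b.sql, dialect)
            + ") AS u"
        )
    return "\nUNION ALL\n".join(rendered)
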