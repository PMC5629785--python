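"""SPARQL SELECT parsing into a small algebra, plus recognition of the
structural patterns the optimizer rewrites.

The supported subset is SPARQL 1.0 SELECT: basic graph patterns, OPTIONAL,
UNION, FILTER (comparisons, IN, arithmetic, boolean connectives, bound()),
and DISTINCT.  Anything else (property paths, subqueries, BIND, VALUES,
aggregates, named graphs, ...) raises :class:`UnsupportedConstructError`.

Patterns of interest:

* **STG** (subject triple group): AND-joined triple patterns sharing one
  subject.  Naive translation self-joins the same logical table once per
  pattern; the optimizer collapses the group to a single scan.
* **OSTG** (STG with optional): an STG or single pattern followed by
  OPTIONAL blocks that each hold a single triple pattern on the same
  subject whose object is a fresh variable.  Eligible for replacing the
  left-outer join by an inner join / single scan.
* **Phantom triple pattern**: ``(s, rdf:type, rdfs:Resource)`` — vacuous
  for any subject the mapping generates — inserted as an anchor so a lone
  OPTIONAL qualifies as an OSTG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from rdflib import RDF, RDFS, Literal, URIRef, Variable
from rdflib.plugins.sparql import algebra as _algebra
from rdflib.plugins.sparql import parser as _parser

__all__ = [
    "UnsupportedConstructError",
    "Term",
    "TriplePattern",
    "GraphPattern",
    "QueryShape",
    "Comparison",
    "LogicalExpr",
    "NotExpr",
    "InExpr",
    "ArithExpr",
    "BoundExpr",
    "parse_query",
    "analyze_query",
    "detect_stg",
    "detect_ostg",
    "insert_phantom",
    "STGGroup",
    "OSTGGroup",
]

RDF_TYPE = str(RDF.type)
RDFS_RESOURCE = str(RDFS.Resource)


class UnsupportedConstructError(Exception):
    """Query uses a construct outside the supported SPARQL subset."""


# --------------------------------------------------------------------------
# terms and patterns


@dataclass(frozen=True)
class Term:
    kind: str  # variable | iri | literal
    lexical: str
    datatype: Optional[str] = None
    language: Optional[str] = None

    @property
    def is_var(self) -> bool:
        return self.kind == "variable"

    def key(self) -> Tuple[str, str, Optional[str], Optional[str]]:
        return (self.kind, self.lexical, self.datatype, self.language)

    def __str__(self) -> str:
        if self.kind == "variable":
            return f"?{self.lexical}"
        if self.kind == "iri":
            return f"<{self.lexical}>"
        return repr(self.lexical)


def var(name: str) -> Term:
    return Term("variable", name)


def iri(value: str) -> Term:
    return Term("iri", value)


@dataclass(frozen=True)
class TriplePattern:
    subject: Term
    predicate: Term
    object: Term
    phantom: bool = False
    pinned_map: Optional[str] = None  # triples map id a phantom is anchored to

    def variables(self) -> Tuple[Term, ...]:
        return tuple(t for t in (self.subject, self.predicate, self.object) if t.is_var)

    def __str__(self) -> str:
        mark = " [phantom]" if self.phantom else ""
        return f"({self.subject} {self.predicate} {self.object}){mark}"


# filter expressions ----------------------------------------------------------


@dataclass(frozen=True)
class Comparison:
    op: str  # = != < <= > >=
    lhs: "FilterNode"
    rhs: "FilterNode"


@dataclass(frozen=True)
class LogicalExpr:
    op: str  # and | or
    operands: Tuple["FilterNode", ...]


@dataclass(frozen=True)
class NotExpr:
    operand: "FilterNode"


@dataclass(frozen=True)
class InExpr:
    lhs: "FilterNode"
    options: Tuple[Term, ...]
    negated: bool = False


@dataclass(frozen=True)
class ArithExpr:
    op: str  # + - * /
    lhs: "FilterNode"
    rhs: "FilterNode"


@dataclass(frozen=True)
class BoundExpr:
    variable: Term


FilterNode = Union[Term, Comparison, LogicalExpr, NotExpr, InExpr, ArithExpr, BoundExpr]


# graph patterns --------------------------------------------------------------


@dataclass
class GraphPattern:
    """Algebra node: TP | AND | OPT | UNION | FILTER | SELECT.

    AND/UNION are n-ary with children in textual order; OPT has exactly two
    children (required side, optional side); FILTER wraps one child; SELECT
    is only ever the root.
    """

    kind: str
    children: List["GraphPattern"] = field(default_factory=list)
    tp: Optional[TriplePattern] = None
    filter_expr: Optional[FilterNode] = None
    projected_vars: Optional[List[str]] = None
    distinct: bool = False

    # constructors
    @staticmethod
    def TP(tp: TriplePattern) -> "GraphPattern":
        return GraphPattern("TP", tp=tp)

    @staticmethod
    def AND(children: Sequence["GraphPattern"]) -> "GraphPattern":
        return GraphPattern("AND", children=list(children))

    @staticmethod
    def OPT(required: "GraphPattern", optional: "GraphPattern") -> "GraphPattern":
        return GraphPattern("OPT", children=[required, optional])

    @staticmethod
    def UNION(children: Sequence["GraphPattern"]) -> "GraphPattern":
        return GraphPattern("UNION", children=list(children))

    @staticmethod
    def FILTER(child: "GraphPattern", expr: FilterNode) -> "GraphPattern":
        return GraphPattern("FILTER", children=[child], filter_expr=expr)

    @staticmethod
    def SELECT(
        child: "GraphPattern", projected: List[str], distinct: bool = False
    ) -> "GraphPattern":
        return GraphPattern(
            "SELECT", children=[child], projected_vars=projected, distinct=distinct
        )

    def triple_patterns(self) -> List[TriplePattern]:
        if self.kind == "TP":
            return [self.tp]  # type: ignore[list-item]
        out: List[TriplePattern] = []
        for c in self.children:
            out.extend(c.triple_patterns())
        return out

    def variables(self) -> Set[str]:
        out: Set[str] = set()
        if self.kind == "TP":
            out.update(t.lexical for t in self.tp.variables())  # type: ignore[union-attr]
        for c in self.children:
            out |= c.variables()
        return out


def required_triple_patterns(gp: GraphPattern) -> List[TriplePattern]:
    """Triple patterns guaranteed to be matched for every solution."""
    if gp.kind == "TP":
        return [gp.tp]  # type: ignore[list-item]
    if gp.kind == "AND":
        out: List[TriplePattern] = []
        for c in gp.children:
            out.extend(required_triple_patterns(c))
        return out
    if gp.kind in ("OPT", "FILTER", "SELECT"):
        return required_triple_patterns(gp.children[0])
    return []  # UNION: no pattern is individually required


def certainly_bound_vars(gp: GraphPattern) -> Set[str]:
    """Variables bound in every solution of the pattern."""
    if gp.kind == "TP":
        return {t.lexical for t in gp.tp.variables()}  # type: ignore[union-attr]
    if gp.kind == "AND":
        out: Set[str] = set()
        for c in gp.children:
            out |= certainly_bound_vars(c)
        return out
    if gp.kind in ("OPT", "FILTER", "SELECT"):
        return certainly_bound_vars(gp.children[0])
    if gp.kind == "UNION":
        sets = [certainly_bound_vars(c) for c in gp.children]
        return set.intersection(*sets) if sets else set()
    return set()


# --------------------------------------------------------------------------
# parsing



def _cv(node, key, default=None):
    """CompValue.get returns the key name itself when absent; normalize
    that to a real default."""
    val = node.get(key)
    if val is None or (isinstance(val, str) and val == key):
        return default
    return val

def _rdflib_term(node) -> Term:
    if isinstance(node, Variable):
        return Term("variable", str(node))
    if isinstance(node, URIRef):
        return Term("iri", str(node))
    if isinstance(node, Literal):
        return Term(
            "literal",
            str(node),
            datatype=str(node.datatype) if node.datatype else None,
            language=node.language,
        )
    raise UnsupportedConstructError(f"unsupported term {node!r}")


def _path_iri(node) -> Term:
    """Unwrap a trivial property path (plain IRI predicate); reject real paths."""
    if isinstance(node, (URIRef, Variable)):
        return _rdflib_term(node)
    name = getattr(node, "name", "")
    if name == "PathAlternative":
        parts = list(node["part"])
        if len(parts) != 1:
            raise UnsupportedConstructError("property paths are not supported")
        return _path_iri(parts[0])
    if name == "PathSequence":
        parts = list(node["part"])
        if len(parts) != 1:
            raise UnsupportedConstructError("property paths are not supported")
        return _path_iri(parts[0])
    if name == "PathElt":
        if _cv(node, "mod") is not None:
            raise UnsupportedConstructError("property paths are not supported")
        return _path_iri(node["part"])
    if name == "PathEltOrInverse":
        raise UnsupportedConstructError("property paths are not supported")
    raise UnsupportedConstructError(f"unsupported predicate {node!r}")


def _convert_expr(node) -> FilterNode:
    if isinstance(node, (Variable, URIRef, Literal)):
        return _rdflib_term(node)
    name = getattr(node, "name", None)
    if name is None:
        raise UnsupportedConstructError(f"unsupported filter expression {node!r}")
    if name in ("ConditionalOrExpression", "ConditionalAndExpression"):
        operands = [_convert_expr(node["expr"])]
        operands += [_convert_expr(o) for o in _cv(node, "other", [])]
        if len(operands) == 1:
            return operands[0]
        return LogicalExpr("or" if "Or" in name else "and", tuple(operands))
    if name == "RelationalExpression":
        lhs = _convert_expr(node["expr"])
        op = _cv(node, "op")
        if op is None:
            return lhs
        if op in ("IN", "NOT IN"):
            opts = []
            for o in node["other"]:
                t = _convert_expr(o)
                if not isinstance(t, Term):
                    raise UnsupportedConstructError("IN list must contain constants")
                opts.append(t)
            return InExpr(lhs, tuple(opts), negated=(op == "NOT IN"))
        return Comparison(op, lhs, _convert_expr(node["other"]))
    if name in ("AdditiveExpression", "MultiplicativeExpression"):
        acc = _convert_expr(node["expr"])
        ops = _cv(node, "op", [])
        others = _cv(node, "other", [])
        for op, other in zip(ops, others):
            acc = ArithExpr(op, acc, _convert_expr(other))
        return acc
    if name == "UnaryNot":
        return NotExpr(_convert_expr(node["expr"]))
    if name == "UnaryMinus":
        zero = Term("literal", "0", datatype="http://www.w3.org/2001/XMLSchema#integer")
        return ArithExpr("-", zero, _convert_expr(node["expr"]))
    if name == "BrackettedExpression":
        return _convert_expr(node["expr"])
    if name == "Builtin_BOUND":
        arg = node["arg"]
        if not isinstance(arg, Variable):
            raise UnsupportedConstructError("bound() requires a variable")
        return BoundExpr(Term("variable", str(arg)))
    raise UnsupportedConstructError(f"unsupported filter construct {name}")


def _and_merge(acc: Optional[GraphPattern], item: GraphPattern) -> GraphPattern:
    if acc is None:
        return item
    parts: List[GraphPattern] = []
    for x in (acc, item):
        if x.kind == "AND":
            parts.extend(x.children)
        else:
            parts.append(x)
    return GraphPattern.AND(parts)


_UNSUPPORTED_PARTS = {
    "Bind": "BIND",
    "InlineData": "VALUES",
    "GraphGraphPattern": "GRAPH",
    "ServiceGraphPattern": "SERVICE",
    "MinusGraphPattern": "MINUS",
    "SubSelect": "subqueries",
}


def _convert_group(node) -> GraphPattern:
    name = getattr(node, "name", None)
    if name == "SubSelect":
        raise UnsupportedConstructError("subqueries are not supported")
    if name != "GroupGraphPatternSub":
        raise UnsupportedConstructError(f"unsupported group {name}")
    acc: Optional[GraphPattern] = None
    filters: List[FilterNode] = []
    for part in _cv(node, "part", []):
        pname = getattr(part, "name", None)
        if pname == "TriplesBlock":
            for trip in part["triples"]:
                items = list(trip)
                if len(items) % 3 != 0:
                    raise UnsupportedConstructError("unsupported triple structure")
                for i in range(0, len(items), 3):
                    s, p, o = items[i : i + 3]
                    tp = TriplePattern(
                        _rdflib_term(s), _path_iri(p), _rdflib_term(o)
                    )
                    if tp.subject.kind == "literal":
                        raise UnsupportedConstructError("literal subject")
                    acc = _and_merge(acc, GraphPattern.TP(tp))
        elif pname == "OptionalGraphPattern":
            inner = _convert_group(part["graph"])
            if acc is None:
                raise UnsupportedConstructError(
                    "OPTIONAL without a preceding required pattern"
                )
            acc = GraphPattern.OPT(acc, inner)
        elif pname == "GroupOrUnionGraphPattern":
            branches = list(part["graph"])
            converted = [_convert_group(b) for b in branches]
            if len(converted) == 1:
                acc = _and_merge(acc, converted[0])
            else:
                acc = _and_merge(acc, GraphPattern.UNION(converted))
        elif pname == "Filter":
            filters.append(_convert_expr(part["expr"]))
        elif pname in _UNSUPPORTED_PARTS:
            raise UnsupportedConstructError(
                f"{_UNSUPPORTED_PARTS[pname]} is not supported"
            )
        else:
            raise UnsupportedConstructError(f"unsupported construct {pname}")
    if acc is None:
        raise UnsupportedConstructError("empty group pattern")
    for f in filters:
        acc = GraphPattern.FILTER(acc, f)
    return acc


def parse_query(text: str) -> GraphPattern:
    """Parse a SPARQL SELECT query into a :class:`GraphPattern` tree rooted
    at a SELECT node.  BGPs are normalized to n-ary AND chains in textual
    order; each FILTER keyword becomes its own FILTER node (applied at the
    end of its group, per SPARQL scoping)."""
    try:
        parsed = _parser.parseQuery(text)
    except Exception as exc:
        raise UnsupportedConstructError(f"cannot parse query: {exc}") from exc
    prologue = _algebra.translatePrologue(parsed[0], None)
    query = _algebra.traverse(
        parsed[1], visitPost=lambda n: _algebra.translatePName(n, prologue)
    )
    if getattr(query, "name", None) != "SelectQuery":
        raise UnsupportedConstructError("only SELECT queries are supported")
    if _cv(query, "datasetClause"):
        raise UnsupportedConstructError("FROM clauses are not supported")
    for key in ("limitoffset", "orderby", "groupby", "having"):
        if _cv(query, key):
            raise UnsupportedConstructError(f"{key} is not supported")
    distinct = _cv(query, "modifier") == "DISTINCT"
    if _cv(query, "modifier") == "REDUCED":
        raise UnsupportedConstructError("REDUCED is not supported")

    body = _convert_group(query["where"])

    projection = _cv(query, "projection")
    if projection:
        projected: List[str] = []
        for pv in projection:
            if _cv(pv, "expr") is not None and _cv(pv, "var") is None:
                raise UnsupportedConstructError("expression projections not supported")
            if _cv(pv, "expr") is not None:
                raise UnsupportedConstructError("AS projections not supported")
            projected.append(str(pv["var"]))
    else:  # SELECT *
        projected = sorted(body.variables())
    return GraphPattern.SELECT(body, projected, distinct=distinct)


# --------------------------------------------------------------------------
# shape analysis


@dataclass(frozen=True)
class QueryShape:
    n_triple_patterns: int
    n_unique_subjects: int
    n_optional_blocks: int
    n_filters: int

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (
            self.n_triple_patterns,
            self.n_unique_subjects,
            self.n_optional_blocks,
            self.n_filters,
        )


def analyze_query(gp: GraphPattern) -> QueryShape:
    """Count triple patterns, distinct subject terms, OPTIONAL blocks
    (nested blocks counted individually) and FILTER patterns.  Phantom
    triple patterns are bookkeeping and excluded from the counts."""
    n_tp = 0
    subjects = set()
    n_opt = 0
    n_filter = 0

    def walk(node: GraphPattern) -> None:
        nonlocal n_tp, n_opt, n_filter
        if node.kind == "TP":
            if not node.tp.phantom:  # type: ignore[union-attr]
                n_tp += 1
                subjects.add(node.tp.subject.key())  # type: ignore[union-attr]
            return
        if node.kind == "OPT":
            n_opt += 1
        elif node.kind == "FILTER":
            n_filter += 1
        for c in node.children:
            walk(c)

    walk(gp)
    return QueryShape(n_tp, len(subjects), n_opt, n_filter)


# --------------------------------------------------------------------------
# STG / OSTG detection


@dataclass
class STGGroup:
    subject: Term
    tps: List[TriplePattern]
    node: GraphPattern  # the AND node holding the run
    start: int  # index of the first TP child in the AND


def detect_stg(gp: GraphPattern) -> List[STGGroup]:
    """Maximal runs (length >= 2) of AND-joined triple patterns sharing a
    subject, in document order."""
    groups: List[STGGroup] = []

    def walk(node: GraphPattern) -> None:
        if node.kind == "AND":
            run: List[TriplePattern] = []
            run_start = 0
            for i, c in enumerate(node.children):
                if c.kind == "TP":
                    tp = c.tp  # type: ignore[assignment]
                    if run and tp.subject.key() == run[0].subject.key():
                        run.append(tp)
                        continue
                    if len(run) >= 2:
                        groups.append(STGGroup(run[0].subject, run, node, run_start))
                    run = [tp]
                    run_start = i
                else:
                    if len(run) >= 2:
                        groups.append(STGGroup(run[0].subject, run, node, run_start))
                    run = []
            if len(run) >= 2:
                groups.append(STGGroup(run[0].subject, run, node, run_start))
        for c in node.children:
            walk(c)

    walk(gp)
    return groups


@dataclass
class OSTGGroup:
    subject: Term
    core: List[TriplePattern]  # required side: single TP or STG
    optionals: List[TriplePattern]  # one per OPTIONAL block, innermost first
    node: GraphPattern  # outermost OPT node of the chain


def _peel_ostg(node: GraphPattern) -> Optional[Tuple[List[TriplePattern], List[TriplePattern]]]:
    if node.kind != "OPT":
        return None
    left, right = node.children
    if right.kind != "TP":
        return None
    rtp: TriplePattern = right.tp  # type: ignore[assignment]
    inner = _peel_ostg(left)
    if inner is not None:
        core, opts = inner
    elif left.kind == "TP":
        core, opts = [left.tp], []  # type: ignore[list-item]
    elif left.kind == "AND" and all(c.kind == "TP" for c in left.children):
        tps = [c.tp for c in left.children]  # type: ignore[misc]
        # the anchoring STG is the maximal suffix run sharing the optional
        # pattern's subject (a phantom anchor lands there)
        core = []
        for t in reversed(tps):
            if t.subject.key() == rtp.subject.key():
                core.insert(0, t)
            else:
                break
        if not core:
            return None
        opts = []
    else:
        return None
    subj = core[0].subject
    if rtp.subject.key() != subj.key():
        return None
    if not rtp.object.is_var:
        return None
    seen = set()
    for t in core + opts:
        seen.update(v.lexical for v in t.variables())
    if rtp.object.lexical in seen:
        return None
    return core, opts + [rtp]


def detect_ostg(gp: GraphPattern) -> List[OSTGGroup]:
    """Maximal OSTG chains: (TP | STG) followed by single-TP OPTIONAL blocks
    on the same subject, each optional object a fresh variable."""
    groups: List[OSTGGroup] = []

    def walk(node: GraphPattern) -> None:
        peeled = _peel_ostg(node)
        if peeled is not None:
            core, opts = peeled
            groups.append(OSTGGroup(core[0].subject, core, opts, node))
            # the chain is fully consumed; its children are TPs only
            return
        for c in node.children:
            walk(c)

    walk(gp)
    return groups


# --------------------------------------------------------------------------
# phantom insertion (optimization O3)


def _generator_maps_for(term: Term, tps: List[TriplePattern], mapping) -> List[str]:
    """Triples maps whose subject the given term is guaranteed to be,
    judged from the required triple patterns that bind it."""
    out: List[str] = []
    for tp in tps:
        if tp.phantom:
            continue
        if tp.object.key() == term.key() and tp.predicate.kind == "iri":
            for tm in mapping.triples_maps:
                for pom in tm.predicate_object_maps:
                    if (
                        pom.predicate_map.kind == "constant"
                        and pom.predicate_map.value == tp.predicate.lexical
                        and pom.is_ref
                    ):
                        out.append(pom.object_map.parent_triples_map)
        if tp.subject.key() == term.key():
            # the subject already has an anchor; phantom not needed, but the
            # map is still a valid generator
            for tm in mapping.triples_maps:
                for pom in tm.predicate_object_maps:
                    if (
                        pom.predicate_map.kind == "constant"
                        and tp.predicate.kind == "iri"
                        and pom.predicate_map.value == tp.predicate.lexical
                    ):
                        out.append(tm.id)
    return list(dict.fromkeys(out))


def insert_phantom(gp: GraphPattern, mapping=None) -> GraphPattern:
    """Insert phantom triple patterns so lone OPTIONALs qualify as OSTGs.

    For an OPT whose optional side is a single triple pattern on subject
    ``s`` with no same-subject anchor in the required side, a pattern
    ``(s, rdf:type, rdfs:Resource)`` is appended to the required side.  The
    insertion is semantics-preserving only when every value of ``s`` is an
    IRI generated by the anchored triples map, so it requires ``s`` to be
    certainly bound in the required side by a term map resolving to exactly
    one candidate triples map (checked against ``mapping`` when provided;
    ambiguity skips the insertion).  Patterns already forming an OSTG are
    returned unchanged.
    """

    def rec(node: GraphPattern) -> GraphPattern:
        if node.kind == "TP":
            return node
        children = [rec(c) for c in node.children]
        node = replace_children(node, children)
        if node.kind != "OPT":
            return node
        left, right = node.children
        if right.kind != "TP":
            return node
        rtp: TriplePattern = right.tp  # type: ignore[assignment]
        subj = rtp.subject
        if not rtp.object.is_var:
            return node
        req = required_triple_patterns(left)
        if any(t.subject.key() == subj.key() for t in req):
            return node  # anchored already (possibly an OSTG)
        if subj.is_var and subj.lexical not in certainly_bound_vars(left):
            return node
        pinned = None
        if mapping is not None:
            candidates = _generator_maps_for(subj, req, mapping)
            if len(candidates) != 1:
                return node  # not inferable / ambiguous: skip, correctness first
            pinned = candidates[0]
        phantom = GraphPattern.TP(
            TriplePattern(
                subject=subj,
                predicate=Term("iri", RDF_TYPE),
                object=Term("iri", RDFS_RESOURCE),
                phantom=True,
                pinned_map=pinned,
            )
        )
        new_left = _and_merge(left, phantom)
        return GraphPattern.OPT(new_left, right)

    def replace_children(node: GraphPattern, children: List[GraphPattern]) -> GraphPattern:
        return GraphPattern(
            kind=node.kind,
            children=children,
            tp=node.tp,
            filter_expr=node.filter_expr,
            projected_vars=node.projected_vars,
            distinct=node.distinct,
        )

    return rec(gp)
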