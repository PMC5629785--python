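"""Execution runtime: run translated SQL, map rows back to RDF-term
bindings, and provide the R2RML materialization oracle used for
semantic-preservation testing.

The translated SQL returns raw database values (so the engine can use its
indexes); this module re-assembles RDF terms from them through the term
maps recorded in the translation's projection metadata.  The
materialization path converts the whole database to an RDF graph by
applying every triples map row by row; evaluating a SPARQL query over that
graph with a standard engine gives the reference answers the translated
SQL must reproduce — the semantic-preservation criterion.
"""

from __future__ import annotations

import csv
import io
import sqlite3
import time
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import rdflib
from rdflib import RDF, Graph, Literal, URIRef

from .r2rml_mappings import (
    MappingDocument,
    RefObjectMap,
    TriplesMap,
    expand_template,
    referenced_columns,
)
from .sparql_patterns import parse_query
from .translator import SRC_ALIAS, TranslatedQuery, VarInfo, render_sql
from . import optimizer as _optimizer

__all__ = [
    "DEFAULT_TIMEOUT_S",
    "QueryTimeoutError",
    "ExecutionError",
    "ResultSet",
    "execute",
    "rows_to_bindings",
    "run_query",
    "translate_query",
    "materialize",
    "canonical_ntriples",
    "evaluate_reference",
]

#: per-query execution timeout (seconds); long-running translations (deeply
#: nested optionals, arithmetic filters) are cut off rather than hanging a
#: session.
DEFAULT_TIMEOUT_S = 300.0


class ExecutionError(Exception):
    """SQL engine error, surfaced with the offending SQL attached."""


class QueryTimeoutError(ExecutionError):
    pass


# --------------------------------------------------------------------------
# result sets


@dataclass
class ResultSet:
    """Ordered list of solution bindings (variable -> rdflib term); an
    unbound variable is simply absent from its binding."""

    variables: List[str]
    bindings: List[Dict[str, object]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bindings)

    def multiset(self) -> Counter:
        """Canonical multiset of solutions (order-insensitive, term-level
        comparison via N3 serialization)."""
        out: Counter = Counter()
        for b in self.bindings:
            out[tuple(sorted((v, t.n3()) for v, t in b.items()))] += 1
        return out

    def to_csv(self, delimiter: str = ",") -> str:
        buf = io.StringIO()
        w = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
        w.writerow(self.variables)
        for b in self.bindings:
            w.writerow([str(b[v]) if v in b else "" for v in self.variables])
        return buf.getvalue()

    def to_dicts(self) -> List[Dict[str, str]]:
        return [{v: str(t) for v, t in b.items()} for b in self.bindings]


def bindings_equal(a: ResultSet, b: ResultSet) -> bool:
    """Multiset equality of solutions (SPARQL SELECT is unordered)."""
    return a.multiset() == b.multiset()


# --------------------------------------------------------------------------
# execution


def execute(
    sql: str,
    connection: sqlite3.Connection,
    timeout: float = DEFAULT_TIMEOUT_S,
) -> Iterator[Dict[str, object]]:
    """Stream rows of a SQL query as ``alias -> value`` dicts."""
    deadline = time.monotonic() + timeout

    def guard():
        if time.monotonic() > deadline:
            return 1  # abort
        return 0

    connection.set_progress_handler(guard, 100_000)
    try:
        cur = connection.cursor()
        try:
            cur.execute(sql)
        except sqlite3.OperationalError as exc:
            if "interrupted" in str(exc):
                raise QueryTimeoutError(f"query timed out after {timeout}s") from exc
            raise ExecutionError(f"{exc}\n-- offending SQL --\n{sql}") from exc
        names = [d[0] for d in cur.description]
        while True:
            try:
                rows = cur.fetchmany(1000)
            except sqlite3.OperationalError as exc:
                raise QueryTimeoutError(
                    f"query timed out after {timeout}s"
                ) from exc
            if not rows:
                break
            for r in rows:
                yield dict(zip(names, r))
    finally:
        connection.set_progress_handler(None, 0)


# --------------------------------------------------------------------------
# rows -> bindings


def _term_from_info(info: VarInfo, row: Dict[str, object]):
    tm = info.term_map
    if tm.kind == "constant":
        if info.indicator is not None and row.get(info.indicator) is None:
            return None
        return expand_template(tm, {})
    cols = referenced_columns(tm)
    values = {c: row.get(a) for c, a in zip(cols, info.aliases)}
    if any(v is None for v in values.values()):
        return None
    try:
        return expand_template(tm, values)
    except Exception as exc:  # datatype violation and the like
        warnings.warn(f"cannot build term for row values {values}: {exc}")
        return Literal(" ".join(str(v) for v in values.values()))


def rows_to_bindings(
    rows: Iterable[Dict[str, object]], tq: TranslatedQuery
) -> ResultSet:
    """Re-assemble RDF terms from raw SQL rows using the translation's
    projection metadata.  A NULL in an optional alias yields an unbound
    variable; multi-column (template) variables follow the R2RML NULL rule.
    """
    variables = list(tq.projected or [])
    rs = ResultSet(variables=variables)
    branch_vars = [b.vars for b in tq.branches]
    multi = len(tq.branches) > 1
    for row in rows:
        idx = int(row[SRC_ALIAS]) if multi else 0
        vars_info = branch_vars[idx]
        binding: Dict[str, object] = {}
        for v in variables or vars_info.keys():
            info = vars_info.get(v)
            if info is None:
                continue
            term = _term_from_info(info, row)
            if term is not None:
                binding[v] = term
        rs.bindings.append(binding)
    return rs


# --------------------------------------------------------------------------
# the serving path


def translate_query(
    query_text: str,
    mapping: MappingDocument,
    meta: Optional["_optimizer.DbMetadata"] = None,
    enabled: Iterable[str] = _optimizer.ALL_OPTIMIZATIONS,
    dialect: str = "sqlite",
) -> Tuple[str, TranslatedQuery]:
    """Parse and translate a SPARQL query; returns (SQL text, translation)."""
    gp = parse_query(query_text)
    tq = _optimizer.optimize(gp, mapping, meta=meta, enabled=enabled)
    return render_sql(tq, dialect), tq


def run_query(
    query_text: str,
    connection: sqlite3.Connection,
    mapping: MappingDocument,
    meta: Optional["_optimizer.DbMetadata"] = None,
    enabled: Iterable[str] = _optimizer.ALL_OPTIMIZATIONS,
    timeout: float = DEFAULT_TIMEOUT_S,
) -> ResultSet:
    """The virtual-endpoint path: SPARQL in, bindings out, touching only
    the relational database."""
    sql, tq = translate_query(query_text, mapping, meta=meta, enabled=enabled)
    return rows_to_bindings(execute(sql, connection, timeout=timeout), tq)


# --------------------------------------------------------------------------
# materialization oracle


def _quoted(name: str) -> str:
    return '"' + name.replace('"', '""') + '"'


def materialize(mapping: MappingDocument, connection: sqlite3.Connection) -> Graph:
    """Apply every triples map to every row, producing the full RDF graph.

    For each row: the subject map gives the subject (plus one ``rdf:type``
    triple per declared class), each predicate-object map gives one triple,
    and ref-object maps are evaluated as inner joins on their join
    conditions.  Rows with NULL in any referenced column produce no triple
    for that term map.
    """
    g = Graph()
    cur = connection.cursor()
    for tm in mapping.triples_maps:
        subj_cols = list(referenced_columns(tm.subject_map))
        plain_poms = [p for p in tm.predicate_object_maps if not p.is_ref]
        cols = list(
            dict.fromkeys(
                subj_cols
                + [c for p in plain_poms for c in referenced_columns(p.object_map)]
                + [c for p in plain_poms for c in referenced_columns(p.predicate_map)]
            )
        )
        if not cols:
            continue
        try:
            rows = cur.execute(
                f"SELECT {', '.join(_quoted(c) for c in cols)} FROM {_quoted(tm.table)}"
            ).fetchall()
        except sqlite3.OperationalError as exc:
            raise ExecutionError(
                f"cannot read logical table {tm.table!r}: {exc}"
            ) from exc
        for r in rows:
            rowd = dict(zip(cols, r))
            subject = expand_template(tm.subject_map, rowd)
            if subject is None:
                continue
            for cls in tm.class_iris:
                g.add((subject, RDF.type, URIRef(cls)))
            for pom in plain_poms:
                pred = expand_template(pom.predicate_map, rowd)
                obj = expand_template(pom.object_map, rowd)
                if pred is None or obj is None:
                    continue
                g.add((subject, pred, obj))
        # ref-object maps: child x parent inner joins
        for pom in tm.predicate_object_maps:
            if not pom.is_ref:
                continue
            rom: RefObjectMap = pom.object_map  # type: ignore[assignment]
            parent = mapping.get(rom.parent_triples_map)
            parent_cols = list(referenced_columns(parent.subject_map))
            sel = [f"c.{_quoted(c)} AS {_quoted('c_' + c)}" for c in subj_cols] + [
                f"p.{_quoted(c)} AS {_quoted('p_' + c)}" for c in parent_cols
            ]
            on = " AND ".join(
                f"c.{_quoted(cc)} = p.{_quoted(pc)}" for cc, pc in rom.join_conditions
            )
            sql = (
                f"SELECT {', '.join(sel)} FROM {_quoted(tm.table)} c "
                f"JOIN {_quoted(parent.table)} p ON {on}"
            )
            for r in cur.execute(sql).fetchall():
                rowd = dict(zip(["c_" + c for c in subj_cols] + ["p_" + c for c in parent_cols], r))
                subject = expand_template(
                    tm.subject_map, {c: rowd["c_" + c] for c in subj_cols}
                )
                obj = expand_template(
                    parent.subject_map, {c: rowd["p_" + c] for c in parent_cols}
                )
                pred = expand_template(pom.predicate_map, {})
                if subject is None or obj is None or pred is None:
                    continue
                g.add((subject, pred, obj))
    return g


def canonical_ntriples(graph: Graph) -> str:
    """Deterministic N-Triples serialization (sorted lines)."""
    lines = sorted(f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph)
    return "\n".join(lines) + ("\n" if lines else "")


def evaluate_reference(query_text: str, graph: Graph) -> ResultSet:
    """Reference SPARQL evaluation over a materialized graph (test oracle
    only; never part of the serving path)."""
    res = graph.query(query_text)
    variables = [str(v) for v in res.vars] if res.vars else []
    rs = ResultSet(variables=variables)
    for row in res:
        binding: Dict[str, object] = {}
        for v in variables:
            val = row[rdflib.Variable(v)]
            if val is not None:
                binding[v] = val
        rs.bindings.append(binding)
    return rs
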