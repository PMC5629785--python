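"""The four optimization families applied to the SPARQL-to-SQL translation.

O1  self-join elimination — subject triple groups are translated as a
    single scan of the shared logical table instead of one self-join per
    triple pattern (``trans_stg``).
O2  left-outer-join removal — subject triple groups with OPTIONAL become
    inner joins (a single scan when O1 is also on) by dropping the IS NOT
    NULL condition of the optional object, whose NULLs then surface as
    unbound variables (``rewrite_ostg``).
O3  phantom triple pattern introduction — a vacuous ``(s, rdf:type,
    rdfs:Resource)`` anchor turns a lone OPTIONAL into an OSTG so O1/O2
    apply.
O4  metadata-driven cleanups — dropping IS NOT NULL on columns the
    database declares non-nullable (``prune_not_null``), joining small
    tables first (``reorder_tables``), and removing union branches whose
    object map cannot match the queried term (``reduce_union``).

The driver (:func:`optimize`) applies them in the order O3 -> O1 -> O2 ->
O4: phantom insertion creates the groups the structural rewrites need, the
group collapse must precede join-type rewriting, and the metadata passes
are purely local and run last.  Every optimization is independently
toggleable; the empty set reproduces the plain translation.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .r2rml_mappings import MappingDocument, TriplesMap
from .sparql_patterns import (
    GraphPattern,
    OSTGGroup,
    STGGroup,
    TriplePattern,
    insert_phantom,
)
from .translator import (
    Branch,
    Col,
    FromItem,
    NotNull,
    SqlQuery,
    TranslatedQuery,
    TranslateFlags,
    Translator,
)

__all__ = [
    "ALL_OPTIMIZATIONS",
    "DbMetadata",
    "collect_metadata",
    "trans_stg",
    "rewrite_ostg",
    "prune_not_null",
    "reorder_tables",
    "reduce_union",
    "optimize",
]

ALL_OPTIMIZATIONS: FrozenSet[str] = frozenset({"O1", "O2", "O3", "O4"})


# --------------------------------------------------------------------------
# database metadata


@dataclass
class DbMetadata:
    """Table statistics and constraints feeding the O4 rewrites."""

    row_counts: Dict[str, int] = field(default_factory=dict)
    non_nullable: Set[Tuple[str, str]] = field(default_factory=set)
    primary_keys: Dict[str, List[str]] = field(default_factory=dict)
    foreign_keys: List[Tuple[str, str, str, str]] = field(default_factory=list)

    def is_non_nullable(self, table: str, column: str) -> bool:
        return (table, column) in self.non_nullable


def collect_metadata(
    connection: sqlite3.Connection,
    view_column_sources: Optional[Dict[Tuple[str, str], Tuple[str, str]]] = None,
) -> DbMetadata:
    """Sample row counts, NOT NULL constraints, and key declarations.

    SQL views carry no constraint declarations of their own; a
    ``view_column_sources`` map ``(view, column) -> (table, column)`` lets a
    view column inherit the nullability of the base column it projects.
    """
    meta = DbMetadata()
    cur = connection.cursor()
    names = [
        r[0]
        for r in cur.execute(
            "SELECT name FROM sqlite_master WHERE type IN ('table','view')"
            " AND name NOT LIKE 'sqlite_%' ORDER BY name"
        )
    ]
    for name in names:
        meta.row_counts[name] = cur.execute(f'SELECT COUNT(*) FROM "{name}"').fetchone()[0]
        pk_cols: List[Tuple[int, str]] = []
        for cid, col, _type, notnull, _dflt, pk in cur.execute(
            f'PRAGMA table_info("{name}")'
        ):
            if notnull or pk:
                meta.non_nullable.add((name, col))
            if pk:
                pk_cols.append((pk, col))
        if pk_cols:
            meta.primary_keys[name] = [c for _, c in sorted(pk_cols)]
        for row in cur.execute(f'PRAGMA foreign_key_list("{name}")'):
            _id, _seq, parent, child_col, parent_col = row[0], row[1], row[2], row[3], row[4]
            if parent_col is None:
                parent_col = (meta.primary_keys.get(parent) or [child_col])[0]
            meta.foreign_keys.append((name, child_col, parent, parent_col))
    if view_column_sources:
        for (view, vcol), (table, tcol) in view_column_sources.items():
            if (table, tcol) in meta.non_nullable:
                meta.non_nullable.add((view, vcol))
    return meta


# --------------------------------------------------------------------------
# O1 / O2 as standalone operations


def trans_stg(
    stg, m: MappingDocument, maps: Optional[Sequence[TriplesMap]] = None
) -> TranslatedQuery:
    """Translate a subject triple group without self-joins: one scan of the
    shared logical table.  Accepts an :class:`STGGroup` or a plain list of
    triple patterns; a group of size one degenerates to the ordinary
    translation."""
    tps = stg.tps if isinstance(stg, STGGroup) else list(stg)
    tr = Translator(m, TranslateFlags(collapse_stg=True))
    return tr.translate_stg(tps, maps)


def rewrite_ostg(
    ostg: OSTGGroup, m: MappingDocument, single_scan: bool = True
) -> TranslatedQuery:
    """Rewrite an OSTG group: the left outer join becomes an inner join
    (single scan when combined with self-join elimination) and the optional
    objects' IS NOT NULL conditions are removed.  Groups whose optional
    patterns resolve to a different logical table than the required side
    are refused and translated with the general left join."""
    tr = Translator(
        m, TranslateFlags(collapse_stg=single_scan, collapse_ostg=True)
    )
    result = tr._try_collapse_ostg(ostg.node)
    if result is not None:
        return result
    return Translator(m).translate(ostg.node)


# --------------------------------------------------------------------------
# O4a: IS NOT NULL pruning


def _alias_env(q: SqlQuery) -> Dict[Optional[str], Optional[str]]:
    env: Dict[Optional[str], Optional[str]] = {}
    base_tables = [f for f in q.from_items if isinstance(f.relation, str)]
    for f in q.from_items:
        if isinstance(f.relation, str):
            env[f.alias] = f.relation
            if f.alias is None:
                env[None] = f.relation
    if len(base_tables) == 1 and base_tables[0].alias is None:
        env[None] = base_tables[0].relation
    return env


def _prune_query(q: SqlQuery, meta: DbMetadata) -> None:
    env = _alias_env(q)
    kept = []
    for cond in q.where:
        if isinstance(cond, NotNull) and isinstance(cond.expr, Col):
            table = env.get(cond.expr.qualifier)
            if table is not None and meta.is_non_nullable(table, cond.expr.column):
                continue
        kept.append(cond)
    q.where = kept
    for f in q.from_items:
        if isinstance(f.relation, SqlQuery):
            _prune_query(f.relation, meta)
    for lj in q.left_joins:
        if isinstance(lj.relation, SqlQuery):
            _prune_query(lj.relation, meta)


def prune_not_null(q, meta: DbMetadata):
    """Drop IS NOT NULL conditions on columns declared non-nullable
    (primary keys, NOT NULL columns); conditions on columns without
    metadata are kept — missing knowledge never removes a filter."""
    if isinstance(q, TranslatedQuery):
        for b in q.branches:
            _prune_query(b.sql, meta)
        return q
    _prune_query(q, meta)
    return q


# --------------------------------------------------------------------------
# O4b: table reordering


def _estimate_rows(rel, meta: DbMetadata) -> Optional[int]:
    if isinstance(rel, str):
        return meta.row_counts.get(rel)
    if isinstance(rel, SqlQuery):
        if len(rel.from_items) == 1 and not rel.left_joins:
            return _estimate_rows(rel.from_items[0].relation, meta)
        return None
    return None


def _reorder_query(q: SqlQuery, meta: DbMetadata) -> None:
    for f in q.from_items:
        if isinstance(f.relation, SqlQuery):
            _reorder_query(f.relation, meta)
    for lj in q.left_joins:
        if isinstance(lj.relation, SqlQuery):
            _reorder_query(lj.relation, meta)
    if len(q.from_items) < 2:
        return
    if any(f.alias is None for f in q.from_items):
        return  # unaliased scan: column references could become ambiguous
    estimates = [_estimate_rows(f.relation, meta) for f in q.from_items]
    if any(e is None for e in estimates):
        return
    order = sorted(range(len(q.from_items)), key=lambda i: estimates[i])
    q.from_items = [q.from_items[i] for i in order]


def reorder_tables(q, meta: DbMetadata):
    """Place smaller relations first among inner-joined from-items (stable:
    equal row counts keep their original order).  Left outer joins are
    never moved across their required side."""
    if isinstance(q, TranslatedQuery):
        for b in q.branches:
            _reorder_query(b.sql, meta)
        return q
    _reorder_query(q, meta)
    return q


# --------------------------------------------------------------------------
# O4c: union reduction


def reduce_union(tp: TriplePattern, m: MappingDocument) -> List[Tuple[str, str]]:
    """Surviving union branches for an unbound-predicate triple pattern:
    ``(triples map id, predicate IRI)`` pairs whose object map is
    compatible with the queried object term.  A literal object eliminates
    IRI-range predicate maps and vice versa; declared-datatype conflicts
    also eliminate."""
    tr = Translator(m, TranslateFlags(reduce_union=True))
    out = []
    for tm, pom, cls in tr._candidates(tp):
        if cls is not None:
            out.append((tm.id, "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"))
        else:
            out.append((tm.id, pom.predicate_map.value))
    return out


# --------------------------------------------------------------------------
# driver


def optimize(
    gp: GraphPattern,
    m: MappingDocument,
    meta: Optional[DbMetadata] = None,
    enabled: Iterable[str] = ALL_OPTIMIZATIONS,
) -> TranslatedQuery:
    """Translate a graph pattern with the selected optimizations.

    ``enabled`` is any subset of {"O1", "O2", "O3", "O4"}; the empty set
    reproduces the unoptimized translation exactly.
    """
    enabled = frozenset(enabled)
    unknown = enabled - ALL_OPTIMIZATIONS
    if unknown:
        raise ValueError(f"unknown optimizations: {sorted(unknown)}")
    if "O3" in enabled:
        gp = insert_phantom(gp, m)
    flags = TranslateFlags(
        collapse_stg="O1" in enabled,
        collapse_ostg="O2" in enabled,
        reduce_union="O4" in enabled,
    )
    tq = Translator(m, flags, meta).translate(gp)
    if "O4" in enabled and meta is not None:
        prune_not_null(tq, meta)
        reorder_tables(tq, meta)
    return tq
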