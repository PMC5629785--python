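"""Optimizations O1-O4: structural effects and result invariance."""

import re
import sqlite3

import pytest

from rimql import (
    collect_metadata,
    detect_ostg,
    insert_phantom,
    optimize,
    parse_mapping,
    parse_query,
    prune_not_null,
    reduce_union,
    render_sql,
    reorder_tables,
    rewrite_ostg,
    trans,
    trans_stg,
)
from rimql.hl7rim_fixture import (
    EXAMPLE6_MAPPING_TTL,
    fixture_metadata,
    query_text,
)
from rimql.runtime import evaluate_reference, execute, run_query, rows_to_bindings
from rimql.sparql_patterns import GraphPattern, Term, TriplePattern
from rimql.translator import SqlQuery, render_sql as render
from tests.conftest import OPT_SUBSETS

EX = "http://example.org/"
HL7 = "http://example.org/hl7rim#"


def v(name):
    return Term("variable", name)


def ex(local):
    return Term("iri", EX + local)


def table_refs(sql: str, table: str) -> int:
    return len(re.findall(rf'(?<![\w"]){re.escape(table)}(?![\w"])', sql.replace('"', "")))


OBS_ATTRS = ["observation_code", "observation_title", "observation_value",
             "observation_valueUnit", "observation_status", "observation_effectiveTime"]


def obs_stg(n):
    """An STG of n triple patterns over the observation view."""
    return [
        TriplePattern(v("o"), Term("iri", HL7 + OBS_ATTRS[k]), v(f"x{k}"))
        for k in range(n)
    ]


class TestTransStg:
    def test_worked_example_collapses_to_single_scan(self, example_mapping):
        tps = [
            TriplePattern(v("p"), ex("hasPatientID"), v("pID")),
            TriplePattern(v("p"), ex("hasPatientName"), v("pName")),
        ]
        sql = render_sql(trans_stg(tps, example_mapping))
        assert table_refs(sql, "v_person") == 1
        for alias in ("var_p", "var_pID", "var_pName"):
            assert alias in sql
        # the unoptimized translation self-joins the table
        naive = render_sql(trans(GraphPattern.AND(
            [GraphPattern.TP(t) for t in tps]), example_mapping))
        assert table_refs(naive, "v_person") == 2

    def test_group_of_one_degenerates_to_plain_translation(self, example_mapping):
        tp = TriplePattern(v("p"), ex("hasPatientID"), v("pID"))
        assert render_sql(trans_stg([tp], example_mapping)) == render_sql(
            trans(GraphPattern.TP(tp), example_mapping)
        )

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_result_multiset_invariant_for_group_sizes(
        self, n, small_mapping, small_conn
    ):
        gp = GraphPattern.AND([GraphPattern.TP(t) for t in obs_stg(n)])
        naive = trans(gp, small_mapping)
        collapsed = trans_stg(obs_stg(n), small_mapping)
        got_a = rows_to_bindings(
            execute(render_sql(naive, "sqlite"), small_conn), naive
        )
        got_b = rows_to_bindings(
            execute(render_sql(collapsed, "sqlite"), small_conn), collapsed
        )
        assert len(got_b) > 0
        assert got_a.multiset() == got_b.multiset()


class TestRewriteOstg:
    def make_pattern(self):
        return GraphPattern.OPT(
            GraphPattern.TP(TriplePattern(v("p"), ex("hasPatientID"), v("pID"))),
            GraphPattern.TP(TriplePattern(v("p"), ex("hasPatientName"), v("name"))),
        )

    def test_left_join_removed_and_not_null_dropped(self, example_mapping):
        groups = detect_ostg(self.make_pattern())
        sql = render_sql(rewrite_ostg(groups[0], example_mapping))
        assert "LEFT" not in sql
        assert table_refs(sql, "v_person") == 1
        assert "patientName IS NOT NULL" not in sql

    def test_null_optional_column_yields_unbound_variable(
        self, example_mapping, example_conn, example_graph
    ):
        qt = (
            f"PREFIX : <{EX}>\n"
            "SELECT ?p ?pID ?name WHERE { ?p :hasPatientID ?pID"
            " OPTIONAL { ?p :hasPatientName ?name } }"
        )
        got = run_query(qt, example_conn, example_mapping)  # all optimizations
        ref = evaluate_reference(qt, example_graph)
        assert got.multiset() == ref.multiset()
        assert any("name" not in b for b in got.bindings)  # patient 3: NULL name

    def test_non_qualifying_group_keeps_left_join(self, example_mapping):
        # optional object variable reused from the required side
        gp = GraphPattern.OPT(
            GraphPattern.TP(TriplePattern(v("p"), ex("hasPatientID"), v("x"))),
            GraphPattern.TP(TriplePattern(v("p"), ex("hasPatientName"), v("x"))),
        )
        assert detect_ostg(gp) == []
        sql = render_sql(optimize(gp, example_mapping))
        assert "LEFT" in sql


class TestPruneNotNull:
    def test_primary_key_condition_dropped_nullable_kept(
        self, small_mapping, small_conn, small_meta
    ):
        gp = parse_query(
            f"PREFIX : <{HL7[:-1]}#>\n"
            "SELECT ?p ?n WHERE { ?p :person_id ?i . ?p :person_name ?n }"
        )
        tq = optimize(gp, small_mapping, enabled={"O1"})
        sql_before = render_sql(tq, "sqlite")
        assert '"patientId" IS NOT NULL' in sql_before
        prune_not_null(tq, small_meta)
        sql_after = render_sql(tq, "sqlite")
        assert '"patientId" IS NOT NULL' not in sql_after
        assert '"patientName" IS NOT NULL' in sql_after

    def test_pruning_preserves_results(self, small_mapping, small_conn, small_meta):
        qt = query_text("q01")
        a = run_query(qt, small_conn, small_mapping, enabled={"O1", "O2", "O3"})
        b = run_query(
            qt, small_conn, small_mapping, meta=small_meta, enabled={"O1", "O2", "O3", "O4"}
        )
        assert a.multiset() == b.multiset()

    def test_missing_metadata_keeps_conditions(self, small_mapping, small_meta):
        from rimql.translator import Col, FromItem, NotNull, SelectItem

        q = SqlQuery(
            select_items=[SelectItem(Col("t", "x"), "x")],
            from_items=[FromItem("no_such_table", "t")],
            where=[NotNull(Col("t", "x"))],
        )
        prune_not_null(q, small_meta)
        assert len(q.where) == 1


class TestReorderTables:
    def scan(self, table, col, alias):
        from rimql.translator import Col, FromItem, SelectItem

        return SqlQuery(
            select_items=[SelectItem(Col(None, col), col)],
            from_items=[FromItem(table, None)],
        )

    def test_smaller_table_joined_first(self, small_meta):
        from rimql.translator import FromItem

        q = SqlQuery(from_items=[
            FromItem(self.scan("act", "actId", "a"), "ta"),
            FromItem(self.scan("person", "patientId", "p"), "tp"),
        ])
        reorder_tables(q, small_meta)
        inner = [f.relation.from_items[0].relation for f in q.from_items]
        assert inner == ["person", "act"]  # 30 rows before 300

    def test_equal_counts_keep_original_order(self, small_meta):
        from rimql.translator import FromItem

        q = SqlQuery(from_items=[
            FromItem(self.scan("person", "patientId", "a"), "t1"),
            FromItem(self.scan("v_person", "patientId", "b"), "t2"),
        ])
        reorder_tables(q, small_meta)
        inner = [f.relation.from_items[0].relation for f in q.from_items]
        assert inner == ["person", "v_person"]

    def test_reordering_preserves_results(self, small_mapping, small_conn, small_meta):
        qt = query_text("q45")
        a = run_query(qt, small_conn, small_mapping, enabled={"O1", "O2", "O3"})
        b = run_query(qt, small_conn, small_mapping, meta=small_meta)
        assert a.multiset() == b.multiset()


class TestReduceUnion:
    def test_literal_object_eliminates_iri_range_branch(self):
        m6 = parse_mapping(EXAMPLE6_MAPPING_TTL)
        tp = TriplePattern(
            Term("iri", EX + "Patient/1"), v("p"), Term("literal", "Bob")
        )
        surviving = reduce_union(tp, m6)
        assert surviving == [("TMapPerson", EX + "hasPatientName")]

    def test_variable_object_removes_nothing(self, example_mapping):
        tp = TriplePattern(v("s"), v("p"), v("o"))
        full = sum(
            1
            for tm in example_mapping.triples_maps
            for _ in tm.predicate_object_maps
        ) + sum(len(tm.class_iris) for tm in example_mapping.triples_maps)
        assert len(reduce_union(tp, example_mapping)) == full

    def test_reduced_union_preserves_results(
        self, example_mapping, example_conn, example_graph
    ):
        qt = f"PREFIX : <{EX}>\nSELECT ?pt ?prop WHERE {{ ?pt ?prop \"Bob\" }}"
        full = run_query(qt, example_conn, example_mapping, enabled=frozenset())
        reduced = run_query(qt, example_conn, example_mapping, enabled={"O4"})
        ref = evaluate_reference(qt, example_graph)
        assert full.multiset() == ref.multiset() == reduced.multiset()


class TestOptimizeDriver:
    def test_empty_set_reproduces_plain_translation(self, example_mapping):
        gp = parse_query(
            f"PREFIX : <{EX}>\n"
            "SELECT ?p ?i ?n WHERE { ?p :hasPatientID ?i . ?p :hasPatientName ?n }"
        )
        assert render_sql(optimize(gp, example_mapping, enabled=frozenset())) == \
            render_sql(trans(gp, example_mapping))

    def test_o1_collapses_worked_example_to_single_scan(self, example_mapping):
        gp = parse_query(
            f"PREFIX : <{EX}>\n"
            "SELECT ?p ?i ?n WHERE { ?p :hasPatientID ?i . ?p :hasPatientName ?n }"
        )
        sql = render_sql(optimize(gp, example_mapping, enabled={"O1"}))
        assert table_refs(sql, "v_person") == 1

    @pytest.mark.parametrize("name", ["q01", "q34", "q45", "q14", "q10", "q_any"])
    def test_soundness_all_subsets_on_fixture(
        self, name, small_mapping, small_conn, small_meta, small_graph
    ):
        """For every optimization subset, optimized and unoptimized
        executions return identical binding multisets, equal to the
        reference evaluation over the materialization."""
        qt = query_text(name)
        ref = evaluate_reference(qt, small_graph).multiset()
        for subset in OPT_SUBSETS:
            got = run_query(
                qt, small_conn, small_mapping, meta=small_meta, enabled=subset
            )
            assert got.multiset() == ref, f"mismatch for subset {sorted(subset)}"

    def test_unknown_optimization_rejected(self, example_mapping):
        gp = parse_query("SELECT ?s WHERE { ?s ?p ?o }")
        with pytest.raises(ValueError):
            optimize(gp, example_mapping, enabled={"O9"})
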