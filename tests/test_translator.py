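"""The alpha/beta mappings, name/genPRSQL/genCondSQL generators, and trans."""

import re

import pytest

from rimql import (
    alpha,
    beta,
    gen_cond_sql,
    gen_name,
    gen_pr_sql,
    parse_mapping,
    parse_query,
    render_sql,
    trans,
)
from rimql.runtime import evaluate_reference, execute, materialize, run_query
from rimql.sparql_patterns import GraphPattern, Term, TriplePattern
from rimql.translator import (
    NameRegistry,
    render_condition,
    render_select_items,
)

EX = "http://example.org/"


def v(name):
    return Term("variable", name)


def ex(local):
    return Term("iri", EX + local)


def ws(s: str) -> str:
    return re.sub(r"\s+", " ", s).strip()


TP_NAME = TriplePattern(v("p"), ex("hasPatientName"), v("pName"))
TP_ID = TriplePattern(v("p"), ex("hasPatientID"), v("pID"))


class TestAlpha:
    def test_mapped_predicate_selects_its_table(self, example_mapping):
        assert [tm.table for tm in alpha(TP_NAME, example_mapping)] == ["v_person"]

    def test_unbound_predicate_selects_all_tables(self, example_mapping):
        tp = TriplePattern(v("s"), v("p"), v("o"))
        assert {tm.table for tm in alpha(tp, example_mapping)} == {
            "v_person",
            "v_observation",
        }

    def test_unknown_predicate_matches_nothing(self, example_mapping):
        tp = TriplePattern(v("s"), ex("unknown"), v("o"))
        assert alpha(tp, example_mapping) == []

    def test_constant_subject_filters_by_template(self, example_mapping):
        tp = TriplePattern(
            Term("iri", EX + "Patient/1"), v("p"), v("o")
        )
        assert {tm.table for tm in alpha(tp, example_mapping)} == {"v_person"}


class TestBeta:
    def test_subject_columns(self, example_mapping):
        cols = beta(TP_NAME, "subject", example_mapping)
        assert [str(c) for c in cols] == ["v_person.patientId"]

    def test_predicate_constant(self, example_mapping):
        assert beta(TP_NAME, "predicate", example_mapping) == "':hasPatientName'"

    def test_object_column(self, example_mapping):
        cols = beta(TP_NAME, "object", example_mapping)
        assert [str(c) for c in cols] == ["v_person.patientName"]

    def test_ref_object_resolves_to_parent_subject_columns(self, example_mapping):
        tp = TriplePattern(v("p"), ex("hasObservation"), v("o"))
        cols = beta(tp, "object", example_mapping)
        assert [str(c) for c in cols] == ["v_observation.actId"]


class TestGenName:
    @pytest.mark.parametrize(
        "term,expected",
        [
            (v("p"), "var_p"),
            (ex("hasPatientName"), "iri_hasPatientName"),
            (v("pName"), "var_pName"),
        ],
    )
    def test_examples(self, term, expected):
        assert gen_name(term) == expected

    def test_injective_within_one_query(self):
        reg = NameRegistry()
        a = reg.name(Term("iri", "http://a.org/thing"))
        b = reg.name(Term("iri", "http://b.org/thing"))
        assert a != b
        # stable on repeat lookups
        assert reg.name(Term("iri", "http://a.org/thing")) == a


class TestGenPrCondSql:
    def test_projection_matches_worked_example(self, example_mapping):
        items = gen_pr_sql(TP_NAME, example_mapping)
        assert ws(render_select_items(items)) == (
            "v_person.patientId AS var_p, "
            "':hasPatientName' AS iri_hasPatientName, "
            "v_person.patientName AS var_pName"
        )

    def test_conditions_match_worked_example(self, example_mapping):
        cond = gen_cond_sql(TP_NAME, example_mapping)
        assert ws(render_condition(cond)).strip("()") == (
            "v_person.patientId IS NOT NULL AND v_person.patientName IS NOT NULL"
        )

    def test_constant_object_adds_equality(self, example_mapping):
        tp = TriplePattern(v("p"), ex("hasPatientName"), Term("literal", "Bob"))
        assert "v_person.patientName = 'Bob'" in render_condition(
            gen_cond_sql(tp, example_mapping)
        )

    def test_constant_subject_inverted_through_template(self, example_mapping):
        tp = TriplePattern(
            Term("iri", EX + "Patient/P1"), ex("hasPatientName"), v("n")
        )
        assert "v_person.patientId = 'P1'" in render_condition(
            gen_cond_sql(tp, example_mapping)
        )


class TestTrans:
    def test_single_pattern_matches_printed_query(self, example_mapping):
        tq = trans(GraphPattern.TP(TP_ID), example_mapping)
        assert ws(render_sql(tq)) == (
            "SELECT patientId AS var_p, patientId AS var_pID "
            "FROM v_person WHERE patientId IS NOT NULL"
        )

    def test_and_joins_on_shared_variable_exactly_once(self, example_mapping):
        gp = GraphPattern.AND([GraphPattern.TP(TP_ID), GraphPattern.TP(TP_NAME)])
        sql = render_sql(trans(gp, example_mapping))
        assert sql.count("var_p = ") + sql.count(".var_p =") >= 1
        assert sql.count("t1.var_p = t2.var_p") == 1

    def test_optional_renders_one_left_join(self, example_mapping):
        gp = GraphPattern.OPT(GraphPattern.TP(TP_ID), GraphPattern.TP(TP_NAME))
        sql = render_sql(trans(gp, example_mapping))
        assert sql.count("LEFT") == 1

    def test_unbound_predicate_becomes_union(self, example_mapping):
        tp = TriplePattern(v("s"), v("p"), v("o"))
        sql = render_sql(trans(GraphPattern.TP(tp), example_mapping))
        assert "UNION ALL" in sql

    def test_unmatchable_pattern_returns_zero_rows(
        self, example_mapping, example_conn
    ):
        tp = TriplePattern(v("s"), ex("unknown"), v("o"))
        sql = render_sql(trans(GraphPattern.TP(tp), example_mapping), "sqlite")
        assert list(execute(sql, example_conn)) == []

    def test_all_constant_pattern_checks_for_a_match(
        self, example_mapping, example_conn
    ):
        hit = TriplePattern(
            Term("iri", EX + "Patient/1"), ex("hasPatientName"), Term("literal", "Bob")
        )
        miss = TriplePattern(
            Term("iri", EX + "Patient/1"), ex("hasPatientName"), Term("literal", "Eve")
        )
        n_hit = len(list(execute(
            render_sql(trans(GraphPattern.TP(hit), example_mapping), "sqlite"),
            example_conn,
        )))
        n_miss = len(list(execute(
            render_sql(trans(GraphPattern.TP(miss), example_mapping), "sqlite"),
            example_conn,
        )))
        assert (n_hit, n_miss) == (1, 0)


class TestRenderSql:
    def test_rendering_is_deterministic(self, example_mapping):
        gp = parse_query(
            f"PREFIX : <{EX}>\n"
            "SELECT ?p ?n WHERE { ?p :hasPatientID ?i"
            " OPTIONAL { ?p :hasPatientName ?n } }"
        )
        a = render_sql(trans(gp, example_mapping), "sqlite")
        b = render_sql(trans(gp, example_mapping), "sqlite")
        assert a == b

    def test_dialect_identifier_quoting(self, example_mapping):
        tq = trans(GraphPattern.TP(TP_ID), example_mapping)
        assert '"patientId"' in render_sql(tq, "sqlite")
        assert "`patientId`" in render_sql(tq, "mysql")
        assert '"patientId"' not in render_sql(tq, "generic")


class TestSemanticPreservationToy:
    """Translated SQL must agree with reference SPARQL over the
    materialization on the worked-example database."""

    @pytest.mark.parametrize(
        "query",
        [
            "SELECT ?p ?n WHERE { ?p :hasPatientName ?n }",
            "SELECT ?p ?i ?n WHERE { ?p :hasPatientID ?i . ?p :hasPatientName ?n }",
            "SELECT ?p ?i ?n WHERE { ?p :hasPatientID ?i OPTIONAL { ?p :hasPatientName ?n } }",
            "SELECT ?x ?v WHERE { { ?x :hasPatientName ?v } UNION { ?x :hasTitle ?v } }",
            "SELECT ?p WHERE { ?p :hasPatientName ?n FILTER (?n = \"Bob\") }",
            "SELECT ?pt ?prop WHERE { ?pt ?prop \"Bob\" }",
            "SELECT DISTINCT ?g WHERE { ?p :hasPatientID ?g }",
        ],
    )
    def test_bindings_match_reference(
        self, query, example_mapping, example_conn, example_graph
    ):
        qt = f"PREFIX : <{EX}>\n" + query
        got = run_query(qt, example_conn, example_mapping, enabled=frozenset())
        ref = evaluate_reference(qt, example_graph)
        assert got.multiset() == ref.multiset()
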