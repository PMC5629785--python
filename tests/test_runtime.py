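"""Execution, result mapping, and the materialization oracle."""

import sqlite3

import pytest
from rdflib import RDF, Literal, URIRef

from rimql import (
    canonical_ntriples,
    evaluate_reference,
    execute,
    materialize,
    parse_mapping,
    parse_query,
    render_sql,
    run_query,
    trans,
)
from rimql.runtime import ExecutionError, rows_to_bindings
from rimql.sparql_patterns import GraphPattern, Term, TriplePattern

EX = "http://example.org/"

RANGE_MAPPING = """\
@prefix rr: <http://www.w3.org/ns/r2rml#> .
@prefix : <http://example.org/> .
<#TMapObs>
    rr:logicalTable [ rr:tableName "obs" ] ;
    rr:subjectMap [ rr:template "http://example.org/Obs/{id}" ] ;
    rr:predicateObjectMap [ rr:predicate :refRange ;
        rr:objectMap [ rr:template "{lo} - {hi}" ; rr:termType rr:Literal ] ] .
"""


@pytest.fixture()
def range_conn():
    conn = sqlite3.connect(":memory:")
    conn.executescript(
        """CREATE TABLE obs (id TEXT PRIMARY KEY, lo INTEGER, hi INTEGER);
           INSERT INTO obs VALUES ('o1', 10, 20), ('o2', NULL, 5);"""
    )
    yield conn
    conn.close()


class TestExecute:
    def test_row_count_matches_table(self, example_mapping, example_conn):
        tp = TriplePattern(
            Term("variable", "p"),
            Term("iri", EX + "hasPatientID"),
            Term("variable", "i"),
        )
        sql = render_sql(trans(GraphPattern.TP(tp), example_mapping), "sqlite")
        assert len(list(execute(sql, example_conn))) == 3

    def test_empty_table(self, example_conn):
        example_conn.execute("DELETE FROM v_observation")
        assert list(execute('SELECT "actId" FROM "v_observation"', example_conn)) == []

    def test_malformed_sql_surfaces_engine_error(self, example_conn):
        with pytest.raises(ExecutionError, match="offending SQL"):
            list(execute("SELECT FROM nowhere", example_conn))


class TestRowsToBindings:
    def test_subject_iri_and_plain_literal(self, example_mapping, example_conn):
        qt = (
            f"PREFIX : <{EX}>\n"
            "SELECT ?p ?n WHERE { ?p :hasPatientName ?n }"
        )
        rs = run_query(qt, example_conn, example_mapping)
        assert {b["p"] for b in rs.bindings} == {
            URIRef(EX + "Patient/1"),
            URIRef(EX + "Patient/2"),
        }
        assert Literal("Bob") in {b["n"] for b in rs.bindings}

    def test_template_columns_reassembled_into_one_literal(self, range_conn):
        m = parse_mapping(RANGE_MAPPING)
        qt = f"PREFIX : <{EX}>\nSELECT ?o ?r WHERE {{ ?o :refRange ?r }}"
        rs = run_query(qt, range_conn, m)
        assert [b["r"] for b in rs.bindings] == [Literal("10 - 20")]

    def test_null_in_optional_alias_is_unbound(self, example_mapping, example_conn):
        qt = (
            f"PREFIX : <{EX}>\n"
            "SELECT ?p ?n WHERE { ?p :hasPatientID ?i"
            " OPTIONAL { ?p :hasPatientName ?n } }"
        )
        rs = run_query(qt, example_conn, example_mapping)
        unbound = [b for b in rs.bindings if "n" not in b]
        assert len(unbound) == 1
        assert unbound[0]["p"] == URIRef(EX + "Patient/3")


class TestMaterialize:
    def test_triple_count_by_hand_enumeration(self, example_mapping, example_conn):
        # 3 persons: 3 type + 3 hasPatientID + 2 hasPatientName (one NULL)
        #            + 3 hasObservation
        # 3 observations: 3 type + 2 hasTitle (one NULL)
        g = materialize(example_mapping, example_conn)
        assert len(g) == 16

    def test_empty_database_gives_empty_graph(self, example_mapping):
        conn = sqlite3.connect(":memory:")
        conn.executescript(
            """CREATE TABLE v_person (patientId TEXT, patientName TEXT,
                                      gender TEXT, actId TEXT);
               CREATE TABLE v_observation (actId TEXT, title TEXT, code TEXT);"""
        )
        assert len(materialize(example_mapping, conn)) == 0

    def test_null_column_skips_only_its_triple(self, example_mapping, example_conn):
        g = materialize(example_mapping, example_conn)
        p3 = URIRef(EX + "Patient/3")
        assert (p3, URIRef(EX + "hasPatientName"), None) not in g
        assert (p3, URIRef(EX + "hasPatientID"), Literal("3")) in g
        assert (p3, RDF.type, URIRef(EX + "Patient")) in g

    def test_unreadable_table_names_it(self, example_mapping):
        conn = sqlite3.connect(":memory:")
        with pytest.raises(ExecutionError, match="v_person|v_observation"):
            materialize(example_mapping, conn)

    def test_canonical_ntriples_deterministic(self, example_mapping, example_conn):
        a = canonical_ntriples(materialize(example_mapping, example_conn))
        b = canonical_ntriples(materialize(example_mapping, example_conn))
        assert a == b
        assert a.splitlines() == sorted(a.splitlines())


class TestEvaluateReference:
    def test_empty_graph_empty_result(self, example_mapping):
        conn = sqlite3.connect(":memory:")
        conn.executescript(
            """CREATE TABLE v_person (patientId TEXT, patientName TEXT,
                                      gender TEXT, actId TEXT);
               CREATE TABLE v_observation (actId TEXT, title TEXT, code TEXT);"""
        )
        g = materialize(example_mapping, conn)
        rs = evaluate_reference("SELECT ?s WHERE { ?s ?p ?o }", g)
        assert len(rs) == 0

    def test_distinct_deduplicates_on_both_paths(
        self, example_mapping, example_conn, example_graph
    ):
        qt = (
            f"PREFIX : <{EX}>\n"
            "SELECT DISTINCT ?t WHERE { ?p a :Patient . ?p ?q ?o . ?p a ?t }"
        )
        got = run_query(qt, example_conn, example_mapping)
        ref = evaluate_reference(qt, example_graph)
        assert got.multiset() == ref.multiset()
        assert len(got) == 1


class TestRoundTrip:
    def test_full_scan_reproduces_materialized_triples(
        self, example_mapping, example_conn, example_graph
    ):
        """Translating (?s ?p ?o) and mapping rows back must reproduce
        exactly the materialized graph's triples (bag = set here, since the
        toy rows generate no duplicate triples)."""
        qt = "SELECT ?s ?p ?o WHERE { ?s ?p ?o }"
        got = run_query(qt, example_conn, example_mapping, enabled=frozenset())
        from_graph = {
            (s.n3(), p.n3(), o.n3()) for s, p, o in example_graph
        }
        from_sql = {
            (b["s"].n3(), b["p"].n3(), b["o"].n3()) for b in got.bindings
        }
        assert from_sql == from_graph
        assert len(got) == len(example_graph)


class TestResultSetOutput:
    def test_csv_output_includes_header_and_blank_unbound(
        self, example_mapping, example_conn
    ):
        qt = (
            f"PREFIX : <{EX}>\n"
            "SELECT ?p ?n WHERE { ?p :hasPatientID ?i"
            " OPTIONAL { ?p :hasPatientName ?n } }"
        )
        rs = run_query(qt, example_conn, example_mapping)
        lines = rs.to_csv().splitlines()
        assert lines[0] == "p,n"
        assert len(lines) == 4
        assert any(line.endswith(",") for line in lines[1:])  # unbound name
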