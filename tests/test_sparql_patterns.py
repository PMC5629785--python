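"""Query parsing, shape analysis, and STG/OSTG/phantom recognition."""

import pytest

from rimql import (
    UnsupportedConstructError,
    analyze_query,
    detect_ostg,
    detect_stg,
    insert_phantom,
    parse_mapping,
    parse_query,
)
from rimql.sparql_patterns import GraphPattern, Term, TriplePattern
from rimql.hl7rim_fixture import EXAMPLE_MAPPING_TTL, QUERY_SHAPES, query_text

EX = "PREFIX : <http://example.org/>\n"


def v(name):
    return Term("variable", name)


def iri(local):
    return Term("iri", "http://example.org/" + local)


def tp(s, p, o):
    return TriplePattern(s, p, o)


class TestParseQuery:
    def test_demographics_query_structure(self):
        gp = parse_query(query_text("q01"))
        assert gp.kind == "SELECT"
        shape = analyze_query(gp)
        assert shape.n_triple_patterns == 4
        assert shape.n_optional_blocks == 1
        assert shape.n_filters == 1

    def test_minimal_query(self):
        gp = parse_query("SELECT ?s WHERE { ?s ?p ?o }")
        assert gp.kind == "SELECT"
        assert gp.children[0].kind == "TP"
        assert gp.projected_vars == ["s"]

    @pytest.mark.parametrize(
        "query",
        [
            EX + "SELECT ?s WHERE { ?s :a/:b ?o }",  # property path
            EX + "SELECT ?s WHERE { ?s :a+ ?o }",
            EX + "SELECT ?s WHERE { ?s :a ?o BIND(?o AS ?x) }",
            EX + "SELECT ?s WHERE { ?s :a ?o } LIMIT 5",
            EX + "SELECT ?s WHERE { VALUES ?s { :x } ?s :a ?o }",
            EX + "SELECT ?s WHERE { { SELECT ?s WHERE { ?s :a ?o } } }",
            EX + "SELECT (COUNT(?s) AS ?n) WHERE { ?s :a ?o }",
            EX + "SELECT ?s WHERE { OPTIONAL { ?s :a ?o } }",
        ],
    )
    def test_unsupported_constructs_are_rejected(self, query):
        with pytest.raises(UnsupportedConstructError):
            parse_query(query)

    def test_bgp_order_is_textual(self):
        gp = parse_query(
            EX + "SELECT * WHERE { ?a :p1 ?x . ?b :p2 ?y . ?a :p3 ?z }"
        )
        body = gp.children[0]
        assert body.kind == "AND"
        preds = [c.tp.predicate.lexical for c in body.children]
        assert [p.rsplit("/", 1)[1] for p in preds] == ["p1", "p2", "p3"]


class TestAnalyzeQuery:
    @pytest.mark.parametrize("name,expected", sorted(QUERY_SHAPES.items()))
    def test_fixture_suite_reproduces_grouping_shapes(self, name, expected):
        shape = analyze_query(parse_query(query_text(name)))
        assert shape.as_tuple() == expected

    def test_single_triple_pattern(self):
        shape = analyze_query(parse_query("SELECT ?s WHERE { ?s ?p ?o }"))
        assert shape.as_tuple() == (1, 1, 0, 0)


class TestDetectStg:
    def test_two_patterns_sharing_subject(self):
        gp = GraphPattern.AND(
            [
                GraphPattern.TP(tp(v("p"), iri("hasPatientID"), v("pID"))),
                GraphPattern.TP(tp(v("p"), iri("hasPatientName"), v("pName"))),
            ]
        )
        groups = detect_stg(gp)
        assert len(groups) == 1 and len(groups[0].tps) == 2

    def test_different_subjects_no_group(self):
        gp = GraphPattern.AND(
            [
                GraphPattern.TP(tp(v("a"), iri("p"), v("x"))),
                GraphPattern.TP(tp(v("b"), iri("q"), v("y"))),
            ]
        )
        assert detect_stg(gp) == []

    def test_maximal_runs_by_subject(self):
        tps = [tp(v("a"), iri(f"p{k}"), v(f"x{k}")) for k in range(5)]
        tps += [tp(v("b"), iri(f"q{k}"), v(f"y{k}")) for k in range(2)]
        gp = GraphPattern.AND([GraphPattern.TP(t) for t in tps])
        assert [len(g.tps) for g in detect_stg(gp)] == [5, 2]


class TestDetectOstg:
    def test_single_optional_same_subject_fresh_object(self):
        gp = GraphPattern.OPT(
            GraphPattern.TP(tp(v("a"), iri("p"), v("x"))),
            GraphPattern.TP(tp(v("a"), iri("q"), v("y"))),
        )
        groups = detect_ostg(gp)
        assert len(groups) == 1
        assert len(groups[0].core) == 1 and len(groups[0].optionals) == 1

    def test_object_reuse_disqualifies(self):
        gp = GraphPattern.OPT(
            GraphPattern.TP(tp(v("a"), iri("p"), v("x"))),
            GraphPattern.TP(tp(v("a"), iri("q"), v("x"))),
        )
        assert detect_ostg(gp) == []

    def test_recursive_chain_of_optionals(self):
        inner = GraphPattern.OPT(
            GraphPattern.AND(
                [
                    GraphPattern.TP(tp(v("a"), iri("p1"), v("x1"))),
                    GraphPattern.TP(tp(v("a"), iri("p2"), v("x2"))),
                ]
            ),
            GraphPattern.TP(tp(v("a"), iri("q1"), v("f1"))),
        )
        outer = GraphPattern.OPT(
            inner, GraphPattern.TP(tp(v("a"), iri("q2"), v("f2")))
        )
        groups = detect_ostg(outer)
        assert len(groups) == 1
        assert len(groups[0].core) == 2 and len(groups[0].optionals) == 2

    def test_detection_is_deterministic(self):
        gp = parse_query(query_text("q10")).children[0]
        first = [(g.subject, [str(t) for t in g.optionals]) for g in detect_ostg(gp)]
        second = [(g.subject, [str(t) for t in g.optionals]) for g in detect_ostg(gp)]
        assert first == second


class TestInsertPhantom:
    LONE_OPT = EX + (
        "SELECT ?p ?o ?t WHERE { ?p :hasObservation ?o"
        " OPTIONAL { ?o :hasTitle ?t } }"
    )

    def test_lone_optional_gains_anchor_and_becomes_ostg(self, example_mapping):
        gp = parse_query(self.LONE_OPT)
        assert detect_ostg(gp) == []
        ph = insert_phantom(gp, example_mapping)
        phantoms = [t for t in ph.triple_patterns() if t.phantom]
        assert len(phantoms) == 1
        assert phantoms[0].pinned_map == "TMapObservation"
        assert len(detect_ostg(ph)) == 1

    def test_insertion_is_idempotent(self, example_mapping):
        ph = insert_phantom(parse_query(self.LONE_OPT), example_mapping)
        again = insert_phantom(ph, example_mapping)
        assert len([t for t in again.triple_patterns() if t.phantom]) == 1

    def test_already_anchored_pattern_unchanged(self, example_mapping):
        gp = parse_query(
            EX + "SELECT * WHERE { ?p :hasPatientID ?i"
            " OPTIONAL { ?p :hasPatientName ?n } }"
        )
        ph = insert_phantom(gp, example_mapping)
        assert [t for t in ph.triple_patterns() if t.phantom] == []

    def test_ambiguous_generator_skips_insertion(self):
        # two maps expose the same linking predicate to different parents:
        # the phantom's target map cannot be inferred, so nothing is added
        doc = parse_mapping(
            """@prefix rr: <http://www.w3.org/ns/r2rml#> .
            @prefix : <http://example.org/> .
            <#M1> rr:logicalTable [ rr:tableName "t1" ] ;
              rr:subjectMap [ rr:template "http://x/A/{i}" ] ;
              rr:predicateObjectMap [ rr:predicate :link ;
                rr:objectMap [ rr:parentTriplesMap <#P1> ;
                  rr:joinCondition [ rr:child "j" ; rr:parent "j" ] ] ] .
            <#M2> rr:logicalTable [ rr:tableName "t2" ] ;
              rr:subjectMap [ rr:template "http://x/B/{i}" ] ;
              rr:predicateObjectMap [ rr:predicate :link ;
                rr:objectMap [ rr:parentTriplesMap <#P2> ;
                  rr:joinCondition [ rr:child "j" ; rr:parent "j" ] ] ] .
            <#P1> rr:logicalTable [ rr:tableName "p1" ] ;
              rr:subjectMap [ rr:template "http://x/C/{j}" ] ;
              rr:predicateObjectMap [ rr:predicate :name ;
                rr:objectMap [ rr:column "n" ] ] .
            <#P2> rr:logicalTable [ rr:tableName "p2" ] ;
              rr:subjectMap [ rr:template "http://x/D/{j}" ] ;
              rr:predicateObjectMap [ rr:predicate :name ;
                rr:objectMap [ rr:column "n" ] ] .
            """
        )
        gp = parse_query(
            EX + "SELECT * WHERE { ?a :link ?o OPTIONAL { ?o :name ?n } }"
        )
        ph = insert_phantom(gp, doc)
        assert [t for t in ph.triple_patterns() if t.phantom] == []
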