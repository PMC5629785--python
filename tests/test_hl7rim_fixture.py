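"""The synthetic clinical fixture: schema, population, mappings, queries."""

import hashlib
import sqlite3

import pytest

from rimql import (
    FixtureConfig,
    analyze_query,
    detect_stg,
    insert_phantom,
    materialize,
    parse_mapping,
    parse_query,
    run_query,
)
from rimql import hl7rim_fixture as fx

EXPECTED_RELATIONS = {
    "act", "observation", "procedure", "substance_administration", "exposure",
    "entity", "person", "role", "participation",
    "act_method_code", "act_target_site_code", "act_approach_site_code",
    "act_observation_interpretation_code", "act_observation_values",
    "v_person", "v_observation", "v_procedure", "v_substanceadministration",
}


class TestBuildSchema:
    def test_all_tables_and_views_exist(self):
        conn = sqlite3.connect(":memory:")
        names = fx.build_schema(conn)
        assert set(names) == EXPECTED_RELATIONS

    def test_rerun_on_populated_database_refuses(self):
        conn = sqlite3.connect(":memory:")
        fx.build_schema(conn)
        with pytest.raises(RuntimeError, match="not empty"):
            fx.build_schema(conn)

    def test_star_join_constraints_declared(self):
        conn = sqlite3.connect(":memory:")
        fx.build_schema(conn)
        fks = conn.execute('PRAGMA foreign_key_list("observation")').fetchall()
        assert any(r[2] == "act" for r in fks)
        info = {r[1]: (r[3], r[5]) for r in conn.execute('PRAGMA table_info("person")')}
        assert info["patientId"][0] == 1  # NOT NULL
        assert info["gender"][0] == 1


class TestPopulate:
    def test_deterministic_database_bytes(self, tmp_path):
        digests = []
        for sub in ("a", "b"):
            path = tmp_path / sub / "fixture.db"
            fx.build_bundle(
                FixtureConfig(seed=7, n_patients=10, n_acts=40, out_dir=path.parent)
            )
            digests.append(hashlib.sha256(path.read_bytes()).hexdigest())
        assert digests[0] == digests[1]

    def test_different_seeds_differ(self, tmp_path):
        digests = []
        for seed in (7, 8):
            out = tmp_path / f"s{seed}"
            fx.build_bundle(
                FixtureConfig(seed=seed, n_patients=10, n_acts=40, out_dir=out)
            )
            digests.append(hashlib.sha256((out / "fixture.db").read_bytes()).hexdigest())
        assert digests[0] != digests[1]

    def test_null_rate_hits_nullable_observation_values(self, small_conn):
        total, nulls = small_conn.execute(
            "SELECT COUNT(*), SUM(value IS NULL) FROM observation"
        ).fetchone()
        frac = nulls / total
        # binomial tolerance: 0.2 +/- 4 sigma at n ~ 160
        assert 0.2 - 0.13 < frac < 0.2 + 0.13

    def test_acts_equal_patients_gives_one_act_each(self):
        conn = sqlite3.connect(":memory:")
        fx.build_schema(conn)
        fx.populate(FixtureConfig(seed=1, n_patients=12, n_acts=12), conn)
        rows = conn.execute(
            "SELECT COUNT(*) FROM participation GROUP BY roleId"
        ).fetchall()
        assert len(rows) == 12 and all(r[0] == 1 for r in rows)

    def test_count_summary_adds_up(self, small_bundle):
        c = small_bundle.manifest["counts"]
        assert (
            c["observations"] + c["procedures"]
            + c["substance_administrations"] + c["exposures"]
            == c["acts"]
        )

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            FixtureConfig(n_patients=10, n_acts=5)
        with pytest.raises(ValueError):
            FixtureConfig(null_rate=1.0)


class TestEmitMappings:
    def test_round_trips_through_parser(self):
        doc = parse_mapping(fx.emit_mappings())
        assert len(doc.triples_maps) == 14

    def test_person_mapped_via_view_not_base_table(self):
        doc = parse_mapping(fx.emit_mappings())
        tables = {tm.table for tm in doc.triples_maps}
        assert "v_person" in tables
        assert "person" not in tables

    def test_ref_range_is_a_two_placeholder_template(self):
        doc = parse_mapping(fx.emit_mappings())
        obs = next(tm for tm in doc.triples_maps if tm.table == "v_observation")
        refrange = next(
            p.object_map
            for p in obs.predicate_object_maps
            if p.predicate_map.value.endswith("observation_refRange")
        )
        assert refrange.kind == "template"
        from rimql import referenced_columns

        assert referenced_columns(refrange) == (
            "referenceRangeMin",
            "referenceRangeMax",
        )


class TestQuerySuite:
    def test_manifest_shapes_match_recomputation(self, small_bundle):
        for name, info in small_bundle.manifest["queries"].items():
            if not info["representative"]:
                continue
            qt = (small_bundle.db_path.parent / info["file"]).read_text()
            assert list(analyze_query(parse_query(qt)).as_tuple()) == info["shape"]

    @pytest.mark.parametrize("name", ["q01", "q10", "q14", "q34", "q45", "q_any"])
    def test_every_query_returns_rows_on_default_seed(
        self, name, small_conn, small_mapping, small_meta
    ):
        rs = run_query(
            fx.query_text(name), small_conn, small_mapping, meta=small_meta
        )
        assert len(rs) >= 1

    def test_manifest_triple_count_matches_materialization(
        self, small_bundle, small_mapping, small_conn
    ):
        g = materialize(small_mapping, small_conn)
        assert len(g) == small_bundle.manifest["expected_triples"]

    def test_suite_exercises_every_optimization_path(self, small_mapping):
        # a subject triple group of size >= 3
        q01 = parse_query(fx.query_text("q01"))
        assert any(len(g.tps) >= 3 for g in detect_stg(q01))
        # a lone OPTIONAL needing a phantom anchor
        ph = insert_phantom(q01, small_mapping)
        assert any(t.phantom for t in ph.triple_patterns())
        # an unbound-predicate pattern for union reduction
        q_any = parse_query(fx.query_text("q_any"))
        assert any(
            t.predicate.is_var for t in q_any.triple_patterns()
        )
        # primary-key IS NOT NULL conditions available for pruning appear in
        # every translated query by construction (subject columns)
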