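import itertools
import sqlite3

import pytest

from rimql import hl7rim_fixture as fx
from rimql import (
    FixtureConfig,
    collect_metadata,
    materialize,
    parse_mapping,
)

#: all 16 subsets of the optimization set
OPT_SUBSETS = [
    frozenset(c)
    for r in range(5)
    for c in itertools.combinations(["O1", "O2", "O3", "O4"], r)
]


@pytest.fixture(scope="session")
def example_mapping():
    return parse_mapping(fx.EXAMPLE_MAPPING_TTL)


@pytest.fixture()
def example_conn():
    conn = sqlite3.connect(":memory:")
    fx.build_example_database(conn)
    yield conn
    conn.close()


@pytest.fixture()
def example_graph(example_mapping, example_conn):
    return materialize(example_mapping, example_conn)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Reduced fixture (30 patients / 300 acts) for fast unit tests."""
    out = tmp_path_factory.mktemp("fx_small")
    return fx.build_bundle(
        FixtureConfig(seed=42, n_patients=30, n_acts=300, out_dir=out)
    )


@pytest.fixture(scope="session")
def small_mapping(small_bundle):
    return parse_mapping(small_bundle.mapping_path.read_text())


@pytest.fixture(scope="session")
def small_conn(small_bundle):
    conn = sqlite3.connect(small_bundle.db_path)
    yield conn
    conn.close()


@pytest.fixture(scope="session")
def small_meta(small_conn):
    return fx.fixture_metadata(small_conn)


@pytest.fixture(scope="session")
def small_graph(small_mapping, small_conn):
    return materialize(small_mapping, small_conn)


@pytest.fixture(scope="session")
def acceptance_bundle(tmp_path_factory):
    """Full-scale fixture (seed 42, 200 patients, 2,000 acts)."""
    out = tmp_path_factory.mktemp("fx_full")
    return fx.build_bundle(
        FixtureConfig(seed=42, n_patients=200, n_acts=2000, out_dir=out)
    )


@pytest.fixture(scope="session")
def acceptance_mapping(acceptance_bundle):
    return parse_mapping(acceptance_bundle.mapping_path.read_text())


@pytest.fixture(scope="session")
def acceptance_conn(acceptance_bundle):
    conn = sqlite3.connect(acceptance_bundle.db_path)
    yield conn
    conn.close()


@pytest.fixture(scope="session")
def acceptance_meta(acceptance_conn):
    return fx.fixture_metadata(acceptance_conn)


@pytest.fixture(scope="session")
def acceptance_graph(acceptance_mapping, acceptance_conn):
    return materialize(acceptance_mapping, acceptance_conn)
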