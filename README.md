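# rimql

A virtual SPARQL endpoint over an HL7-RIM-style clinical relational
database.  R2RML mappings relate an HL7 v3 Reference Information Model
vocabulary (Act with its Observation / Procedure / SubstanceAdministration /
Exposure subclasses, Entity/Person, Role, Participation) to a relational
star schema; SPARQL SELECT queries are translated on the fly into SQL,
executed against the live database, and the rows are mapped back into RDF
bindings.  Nothing is materialized in the serving path, so results are
always fresh — the use case is clinical-trial cohort and patient-recruitment
queries over an interoperability data model, for people who want to query
relational clinical data through an ontology vocabulary without an ETL step.

## The translation

For a triple pattern *tp* under an R2RML mapping document *m*:

* **α**(tp, m) — the logical tables (triples maps) the pattern can draw
  from, selected by its predicate (and constant subject, inverted through
  the subject template);
* **β**(tp, position, m) — the columns behind each position of the pattern;
  objects reached through a ref-object map resolve to the parent's subject
  columns;
* **name** — a deterministic, injective alias per term
  (`?p → var_p`, `:hasPatientName → iri_hasPatientName`);
* **genPRSQL** — the projection: β columns renamed through *name*;
* **genCondSQL** — the conditions: `IS NOT NULL` on every β column, plus
  equalities for constant terms (template-inverted where possible);
* **trans** — the compositional translation of whole graph patterns:
  AND → inner join on shared-variable aliases, OPTIONAL → left outer join,
  UNION → branch union with aligned projections, FILTER → WHERE, SELECT →
  outer projection.

Four optimization families rewrite the naive output:

* **O1 self-join elimination** — AND-joined patterns sharing a subject (a
  *subject triple group*, STG) become a single scan of their shared table
  instead of one self-join per pattern;
* **O2 left-outer-join removal** — single-pattern OPTIONALs on the same
  subject and table (an *OSTG*) become inner joins / the same single scan,
  by dropping the optional object's `IS NOT NULL`; the column's NULLs then
  surface as unbound variables;
* **O3 phantom triple patterns** — a vacuous `(s, rdf:type, rdfs:Resource)`
  anchor is inserted so an unanchored OPTIONAL qualifies for O2;
* **O4 metadata cleanups** — `IS NOT NULL` dropped on columns the database
  declares non-nullable, smaller tables joined first, and union branches
  whose object map cannot match the queried term removed.

Correctness is *semantic preservation*: the translated SQL returns the same
binding multiset as the same SPARQL query evaluated over an R2RML
materialization of the same database.  The test suite checks this for every
query in the bundled suite under all 16 optimization subsets, with rdflib
as the independent reference SPARQL engine.

## Worked example

Two tables: `v_person(patientId, patientName, gender, actId)` and
`v_observation(actId, title, code)`, mapped to a `Patient` class keyed by
`patientId` with `hasPatientID` / `hasPatientName` properties and a
`hasObservation` link.

```python
import sqlite3
from rimql import parse_mapping, translate_query, run_query, materialize
from rimql.hl7rim_fixture import EXAMPLE_MAPPING_TTL, build_example_database

m = parse_mapping(EXAMPLE_MAPPING_TTL)
conn = sqlite3.connect(":memory:")
build_example_database(conn)

q = """PREFIX : <http://example.org/>
SELECT ?p ?pID ?name WHERE {
  ?p :hasPatientID ?pID .
  OPTIONAL { ?p :hasPatientName ?name }
}"""
sql, _ = translate_query(q, m)   # one scan: the OPTIONAL collapsed (O1+O2)
print(run_query(q, conn, m).to_csv())
```

prints

```
p,pID,name
http://example.org/Patient/1,1,Bob
http://example.org/Patient/2,2,Alice
http://example.org/Patient/3,3,
```

one row per person; patient 3 has a NULL `patientName`, so `?name` comes
back unbound (the empty cell) rather than dropping the row — exactly the
OPTIONAL semantics the left-join-free translation must keep.  The generated
SQL references `v_person` once, with no left outer join and no
`patientName IS NOT NULL` condition.

## The fixture

`rimql fixture --seed 42 --patients 200 --acts 2000 --out-dir fixtures/`
generates a seeded synthetic clinical database (RIM star schema plus
per-context views), its R2RML mapping document (14 triples maps, built by
direct mapping, view substitution, and template steps), five representative
clinical queries with fixed shape tuples (triple patterns / unique subjects
/ OPTIONAL blocks / FILTERs): demographics (4/2/1/1), substance
administration (35/9/21/1), laboratory results with a body-mass-index
arithmetic filter (15/6/5/2), procedure (6/3/1/1), observation (14/5/4/2),
plus an auxiliary unbound-predicate probe, and a manifest with the expected
shapes and the independently counted materialized-triple total.

Other CLI verbs: `rimql query --db … --mapping … --query … [--disable-opt
O1,O2]`, `rimql translate` (prints SQL only), `rimql materialize --out
graph.nt`.

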