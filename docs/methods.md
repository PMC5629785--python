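# Methods

## The model

The engine implements ontology-based data access by query translation: a
SPARQL SELECT query over an HL7-RIM-flavoured vocabulary is rewritten, via
R2RML mappings, into a single SQL query over the relational database that
stores the clinical data, and the returned rows are mapped back into RDF
terms.  The correctness notion is **semantic preservation**: the translated
SQL must return the same multiset of bindings as the same SPARQL query
evaluated over the R2RML materialization of the same database state.  The
materialization path (and a standard SPARQL engine, rdflib, on top of it)
therefore serves as the test oracle; it is never part of the serving path.

### Translation

Each triple pattern becomes a scan of the logical table(s) selected by the
α mapping, projecting the β columns of its variable positions under aliases
from the *name* function, and filtering `IS NOT NULL` on every referenced
column (a NULL column generates no triple under R2RML, so a NULL row can
never be a pattern match).  Raw column values — not expanded IRIs — travel
through the SQL, so the database can use its indexes; the runtime
re-assembles terms afterwards from per-alias projection metadata (term map
plus column aliases, carried per union branch with a `__src` discriminator
column).

Compositionally: AND joins child queries on shared-variable alias equality
(column-wise when the two term maps share a template skeleton, otherwise on
the string-expansion expressions); OPTIONAL is a left outer join whose
required side keeps its NOT-NULL conditions; UNION concatenates branches
with lexicographically aligned, NULL-padded projections; FILTER compiles to
a WHERE condition over the child's aliases (a comparison over an unbound
variable is a SPARQL type error and compiles to FALSE; `bound()` becomes an
`IS NOT NULL` test, with a constant match-indicator column for variables
bound to constants on optional sides); SELECT projects the requested
variables and applies DISTINCT when asked.

Constant subjects and objects are pushed down to column equalities by
inverting the term map's template.  A template is invertible when no two
placeholders are adjacent; non-invertible templates fall back to comparing
the expanded string expression, which is correct but forgoes index use.

### Optimizations

Applied in the order **O3 → O1 → O2 → O4**: phantom insertion first (it
creates the anchored groups the structural rewrites need), group collapse
before join-type rewriting, metadata passes last because they are purely
local.  Every optimization is independently toggleable; the empty set
reproduces the naive translation exactly, which is what makes the effect of
each family measurable.

* **O1** translates a subject triple group as one scan: union of the
  per-pattern projections, conjunction of the per-pattern conditions.
  Groups whose patterns resolve to different logical tables are split.
* **O2** applies to OPTIONAL blocks holding a single triple pattern whose
  subject matches a run of required patterns and whose object is a fresh
  variable mapped to a plain column/template of the *same* logical table.
  The left outer join becomes an inner join (with O1, the same single
  scan), minus the optional object's `IS NOT NULL`.  The rewrite also
  regroups: an anchor run anywhere in the required side is used, which is
  sound because inner joins commute and the optional pattern shares only
  its subject with the rest of the query.  Soundness additionally assumes
  the subject column identifies the row (the fixture's subject templates
  are all over primary keys); optional patterns whose object is a
  ref-object join, whose predicate maps elsewhere, or whose optional side
  is a nested group are conservatively left as left outer joins.
* **O3** inserts `(s, rdf:type, rdfs:Resource)` as an anchor only when the
  optional's subject is certainly bound in the required side and its
  generating term map resolves to exactly one triples map (found through
  ref-object links or subject maps); anything ambiguous is skipped.  The
  phantom contributes one subject-non-NULL scan and is never projected.
* **O4** prunes `IS NOT NULL` on columns the metadata declares non-nullable
  (view columns inherit the constraint of the base column they project,
  through an explicit provenance table, since views declare nothing
  themselves); reorders inner-joined relations ascending by sampled row
  count (stable, never across a left join); and removes union branches of
  unbound-predicate patterns whose object map's term kind or declared
  datatype contradicts the queried constant.  Metadata is sampled once per
  connection; a CLI flag re-samples.

### Numerical and lexical choices

One shared `lexical_form` converts SQL values to literal lexical forms on
both the materialization and the serving path, so the two routes always
print identical literals (floats with a trailing `.0` render as `65.0`).
Numeric filter arithmetic runs natively in SQL; the oracle computes the
same expressions in exact decimal.  The two can only disagree within
floating-point distance of a comparison threshold, which the fixture's
two-decimal value grid keeps away from its thresholds.  Identifiers are
quoted in the sqlite and mysql dialects; the `generic` dialect quotes only
when necessary, which keeps simple translations readable.  Rendered SQL is
a pure function of the query AST.  In the sqlite dialect every derived
table carries a `LIMIT -1` clause: sqlite's query flattener would otherwise
merge the per-pattern subqueries into one join, whose width is capped at 64
relations — a cap the naive translation of the 35-pattern query would
exceed.

## The fixture

Defaults: 200 patients, 2,000 acts (the 1:10 patient-to-act ratio of a
several-month clinical extract, at desk scale), 20% of nullable clinical
attributes NULL so every OPTIONAL path is exercised in both directions, one
`SBJ` participation per act, codes from a small internal list.  Acts are
dealt round-robin; the first patient's acts are scripted (an anemia finding
with interpretation, weight 65.0 kg and height 1.70 m giving a body-mass
index of 22.5, a T2 tumor observation with target site, a chemotherapy
procedure, a diphosphonate administration with method/target/approach
sites, a titled observation, an exposure) so that each representative query
returns at least one solution for any seed.  Everything is driven by one
`random.Random(seed)`; the database bytes are identical across runs of the
same configuration.

What the generator does **not** emulate: clinical plausibility beyond
structure, terminology bindings (no SNOMED/LOINC), duplicate subject rows,
language-tagged literals, blank nodes, and multi-column keys.  Passing
tests therefore demonstrate translation correctness over a star schema with
single-column primary-key subjects and plain/xsd-typed literals — the
configuration the engine targets — not robustness to arbitrary R2RML.

## Problem sizes in the test suite

Unit tests run against a 30-patient / 300-act bundle; the acceptance tests
and `scripts/acceptance.py` rebuild the full 200 / 2,000 configuration and
evaluate the five representative queries under all 16 optimization subsets
against a fresh materialization (~43,000 triples).  The whole suite runs in
about a minute on one CPU; the reference evaluation of the
laboratory-results query (three correlated observation joins plus
arithmetic) dominates.

## Known limitations

* Bag semantics are implemented by reading table rows directly; if a
  logical table contained duplicate rows, the SQL path would return
  duplicate solutions where a graph (a set of triples) would not.  With
  primary-key subjects the two coincide.
* `DISTINCT` deduplicates per union branch on raw column values; identical
  bindings produced by *different* union branches are not merged.  No
  mapped predicate produces such cross-branch duplicates here.
* OPTIONAL translation assumes well-designed patterns: a variable shared
  between an optional side and a *later* sibling pattern (but missing from
  the required side) would need SPARQL's compatible-bindings semantics,
  which SQL NULL-equality does not provide.
* Union inside an OPTIONAL's optional side (e.g. an unbound predicate
  there) is rejected rather than translated.
* Join equality on expansion expressions compares pre-percent-encoding
  strings; column values containing IRI-reserved characters in multi-column
  templates could in principle collide.  Single-column keys cannot.
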