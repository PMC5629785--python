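"""Synthetic HL7-RIM-style clinical database, its R2RML mapping document,
and a SPARQL query suite — a self-contained, seeded test bed for the
translation engine.

The schema follows the RIM backbone: an ``act`` fact table with the
subclass tables ``observation``, ``procedure``, ``substance_administration``
and ``exposure``; ``entity``/``person`` dimensions linked through ``role``
and ``participation``; and small act-code lookup tables (method, target
site, approach site, interpretation, observation values).  Per-context SQL
views (``v_person``, ``v_observation``, ``v_procedure``,
``v_substanceadministration``) denormalize the star joins the way a
clinical data warehouse would.

The mapping document is produced by the three-step methodology the engine
is designed for: (1) a direct-mapping-style triples map per table, with
ref-object maps for the foreign keys; (2) tables that have a context view
are mapped through the view instead; (3) template properties for values
spanning several columns, e.g. the observation reference range
``"{referenceRangeMin} - {referenceRangeMax}"``.

The query suite emulates five representative clinical query shapes —
demographics, substance administration, laboratory results (with an
arithmetic body-mass-index filter), procedure, and observation — with
fixed triple-pattern/subject/OPTIONAL/FILTER counts, plus one auxiliary
unbound-predicate query exercising union reduction.

Only structure is emulated: codes come from a tiny internal list, values
are uniform draws, and no terminology binding or clinical plausibility
beyond the query requirements is attempted.
"""

from __future__ import annotations

import datetime
import json
import random
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .r2rml_mappings import MappingDocument, parse_mapping

__all__ = [
    "ONT",
    "RES",
    "FixtureConfig",
    "FixtureBundle",
    "build_schema",
    "populate",
    "emit_mappings",
    "emit_query_suite",
    "build_bundle",
    "expected_triple_count",
    "fixture_metadata",
    "VIEW_COLUMN_SOURCES",
    "EXAMPLE_MAPPING_TTL",
    "EXAMPLE6_MAPPING_TTL",
    "build_example_database",
]

ONT = "http://example.org/hl7rim#"
RES = "http://example.org/hl7rim/"


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FixtureConfig:
    """Fixture scale and noise knobs.

    Defaults are 200 patients and 2,000 acts — a roughly 1:10 patient:act
    ratio at desk scale — with 20% of the nullable clinical attributes
    NULL, which keeps every OPTIONAL/left-join path exercised.
    """

    seed: int = 42
    n_patients: int = 200
    n_acts: int = 2000
    null_rate: float = 0.2
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.n_acts < self.n_patients:
            raise ValueError("n_acts must be >= n_patients")
        if not (0 <= self.null_rate < 1):
            raise ValueError("null_rate must be in [0, 1)")


@dataclass
class FixtureBundle:
    db_path: Path
    mapping_path: Path
    query_paths: Dict[str, Path]
    manifest: Dict
    manifest_path: Path


# --------------------------------------------------------------------------
# schema

_SCHEMA_SQL = """
CREATE TABLE entity (
    entityId TEXT PRIMARY KEY,
    classCode TEXT NOT NULL,
    determinerCode TEXT
);
CREATE TABLE person (
    entityId TEXT PRIMARY KEY REFERENCES entity(entityId),
    patientId TEXT NOT NULL UNIQUE,
    patientName TEXT,
    gender TEXT NOT NULL,
    birthTime TEXT NOT NULL,
    maritalStatusCode TEXT
);
CREATE TABLE role (
    roleId TEXT PRIMARY KEY,
    entityId TEXT NOT NULL REFERENCES entity(entityId),
    classCode TEXT NOT NULL
);
CREATE TABLE act (
    actId TEXT PRIMARY KEY,
    classCode TEXT NOT NULL,
    moodCode TEXT NOT NULL,
    code TEXT NOT NULL,
    title TEXT,
    effectiveTime TEXT NOT NULL,
    statusCode TEXT
);
CREATE TABLE participation (
    participationId TEXT PRIMARY KEY,
    actId TEXT NOT NULL REFERENCES act(actId),
    roleId TEXT NOT NULL REFERENCES role(roleId),
    typeCode TEXT NOT NULL
);
CREATE TABLE observation (
    actId TEXT PRIMARY KEY REFERENCES act(actId),
    value REAL,
    valueUnit TEXT,
    referenceRangeMin REAL,
    referenceRangeMax REAL,
    interpretationCode TEXT REFERENCES act_observation_interpretation_code(code),
    methodCode TEXT REFERENCES act_method_code(code),
    targetSiteCode TEXT REFERENCES act_target_site_code(code)
);
CREATE TABLE "procedure" (
    actId TEXT PRIMARY KEY REFERENCES act(actId),
    methodCode TEXT REFERENCES act_method_code(code),
    targetSiteCode TEXT REFERENCES act_target_site_code(code),
    approachSiteCode TEXT REFERENCES act_approach_site_code(code)
);
CREATE TABLE substance_administration (
    actId TEXT PRIMARY KEY REFERENCES act(actId),
    doseQuantity REAL,
    routeCode TEXT,
    methodCode TEXT REFERENCES act_method_code(code),
    targetSiteCode TEXT REFERENCES act_target_site_code(code),
    approachSiteCode TEXT REFERENCES act_approach_site_code(code)
);
CREATE TABLE exposure (
    actId TEXT PRIMARY KEY REFERENCES act(actId),
    typeCode TEXT
);
CREATE TABLE act_method_code (
    code TEXT PRIMARY KEY, name TEXT NOT NULL, description TEXT
);
CREATE TABLE act_target_site_code (
    code TEXT PRIMARY KEY, name TEXT NOT NULL, description TEXT
);
CREATE TABLE act_approach_site_code (
    code TEXT PRIMARY KEY, name TEXT NOT NULL, description TEXT
);
CREATE TABLE act_observation_interpretation_code (
    code TEXT PRIMARY KEY, name TEXT NOT NULL
);
CREATE TABLE act_observation_values (
    code TEXT PRIMARY KEY, label TEXT NOT NULL
);
CREATE VIEW v_person AS
    SELECT p.patientId AS patientId, p.patientName AS patientName,
           p.gender AS gender, p.birthTime AS birthTime
    FROM person p;
CREATE VIEW v_observation AS
    SELECT o.actId AS actId, per.patientId AS patientId, a.code AS code,
           a.title AS title, a.effectiveTime AS effectiveTime,
           a.statusCode AS statusCode, o.value AS value,
           o.valueUnit AS valueUnit,
           o.referenceRangeMin AS referenceRangeMin,
           o.referenceRangeMax AS referenceRangeMax,
           o.interpretationCode AS interpretationCode,
           o.methodCode AS methodCode, o.targetSiteCode AS targetSiteCode
    FROM observation o
    JOIN act a ON o.actId = a.actId
    JOIN participation pt ON pt.actId = a.actId
    JOIN role r ON pt.roleId = r.roleId
    JOIN person per ON per.entityId = r.entityId;
CREATE VIEW v_procedure AS
    SELECT pr.actId AS actId, per.patientId AS patientId, a.code AS code,
           a.title AS title, a.effectiveTime AS effectiveTime,
           a.statusCode AS statusCode, pr.methodCode AS methodCode,
           pr.targetSiteCode AS targetSiteCode,
           pr.approachSiteCode AS approachSiteCode
    FROM "procedure" pr
    JOIN act a ON pr.actId = a.actId
    JOIN participation pt ON pt.actId = a.actId
    JOIN role r ON pt.roleId = r.roleId
    JOIN person per ON per.entityId = r.entityId;
CREATE VIEW v_substanceadministration AS
    SELECT sa.actId AS actId, per.patientId AS patientId, a.code AS code,
           a.title AS title, a.effectiveTime AS effectiveTime,
           a.statusCode AS statusCode, sa.doseQuantity AS doseQuantity,
           sa.routeCode AS routeCode, sa.methodCode AS methodCode,
           sa.targetSiteCode AS targetSiteCode,
           sa.approachSiteCode AS approachSiteCode
    FROM substance_administration sa
    JOIN act a ON sa.actId = a.actId
    JOIN participation pt ON pt.actId = a.actId
    JOIN role r ON pt.roleId = r.roleId
    JOIN person per ON per.entityId = r.entityId;
"""

#: view column -> base column provenance, used to let the optimizer's
#: metadata pass inherit NOT NULL constraints through the views.
VIEW_COLUMN_SOURCES: Dict[Tuple[str, str], Tuple[str, str]] = {}
for _view, _cols in {
    "v_person": {
        "patientId": ("person", "patientId"),
        "patientName": ("person", "patientName"),
        "gender": ("person", "gender"),
        "birthTime": ("person", "birthTime"),
    },
    "v_observation": {
        "actId": ("observation", "actId"),
        "patientId": ("person", "patientId"),
        "code": ("act", "code"),
        "title": ("act", "title"),
        "effectiveTime": ("act", "effectiveTime"),
        "statusCode": ("act", "statusCode"),
        "value": ("observation", "value"),
        "valueUnit": ("observation", "valueUnit"),
        "referenceRangeMin": ("observation", "referenceRangeMin"),
        "referenceRangeMax": ("observation", "referenceRangeMax"),
        "interpretationCode": ("observation", "interpretationCode"),
        "methodCode": ("observation", "methodCode"),
        "targetSiteCode": ("observation", "targetSiteCode"),
    },
    "v_procedure": {
        "actId": ("procedure", "actId"),
        "patientId": ("person", "patientId"),
        "code": ("act", "code"),
        "title": ("act", "title"),
        "effectiveTime": ("act", "effectiveTime"),
        "statusCode": ("act", "statusCode"),
        "methodCode": ("procedure", "methodCode"),
        "targetSiteCode": ("procedure", "targetSiteCode"),
        "approachSiteCode": ("procedure", "approachSiteCode"),
    },
    "v_substanceadministration": {
        "actId": ("substance_administration", "actId"),
        "patientId": ("person", "patientId"),
        "code": ("act", "code"),
        "title": ("act", "title"),
        "effectiveTime": ("act", "effectiveTime"),
        "statusCode": ("act", "statusCode"),
        "doseQuantity": ("substance_administration", "doseQuantity"),
        "routeCode": ("substance_administration", "routeCode"),
        "methodCode": ("substance_administration", "methodCode"),
        "targetSiteCode": ("substance_administration", "targetSiteCode"),
        "approachSiteCode": ("substance_administration", "approachSiteCode"),
    },
}.items():
    for _vcol, _src in _cols.items():
        VIEW_COLUMN_SOURCES[(_view, _vcol)] = _src


def build_schema(connection: sqlite3.Connection) -> List[str]:
    """Create the RIM star schema and its context views on an empty
    database; refuses to run on a non-empty one."""
    cur = connection.cursor()
    existing = cur.execute(
        "SELECT name FROM sqlite_master WHERE name NOT LIKE 'sqlite_%'"
    ).fetchall()
    if existing:
        raise RuntimeError("refusing to build schema: database is not empty")
    cur.executescript(_SCHEMA_SQL)
    connection.commit()
    return [
        r[0]
        for r in cur.execute(
            "SELECT name FROM sqlite_master WHERE type IN ('table','view')"
            " AND name NOT LIKE 'sqlite_%' ORDER BY name"
        )
    ]


def fixture_metadata(connection: sqlite3.Connection):
    """Database metadata for the optimizer, with view columns inheriting
    the nullability of the base columns they project."""
    from .optimizer import collect_metadata

    return collect_metadata(connection, view_column_sources=VIEW_COLUMN_SOURCES)


# --------------------------------------------------------------------------
# population

_METHODS = [
    ("M1", "Intravenous infusion", "Continuous infusion through a peripheral line"),
    ("M2", "Palpation", None),
    ("M3", "Ultrasound guided", "Imaging-guided technique"),
    ("M4", "Oral administration", None),
    ("M5", "Biopsy needle", "Core needle sampling"),
]
_TARGET_SITES = [
    ("TS1", "Arm", None),
    ("TS2", "Breast", "Left or right breast"),
    ("TS3", "Axilla", None),
    ("TS4", "Abdomen", "Abdominal wall"),
    ("TS5", "Thorax", None),
]
_APPROACH_SITES = [
    ("AS1", "Peripheral vein", None),
    ("AS2", "Skin", "Percutaneous"),
    ("AS3", "Oral cavity", None),
    ("AS4", "Central line", "Subclavian access"),
]
_INTERPRETATIONS = [("L", "Below reference range"), ("N", "Normal"), ("H", "Above reference range")]
_OBS_VALUE_CODES = [("OV1", "Positive"), ("OV2", "Negative"), ("OV3", "Indeterminate")]

_OBS_CODES = ["WEIGHT", "HEIGHT", "GLUCOSE", "HEMOGLOBIN", "ANEMIA", "TUMOR-T2", "BLOOD-PRESSURE"]
_PROC_CODES = ["CHEMO-1", "CHEMO-2", "BIOPSY", "MASTECTOMY", "RADIO-1"]
_SA_CODES = ["DIPHOS", "TAMOXIFEN", "ANTIBIOTIC-1", "ANALGESIC-1"]
_SA_WEIGHTS = [1, 3, 3, 3]
_EXPOSURE_CODES = ["ENV", "RAD", "CHEM"]
_FIRST_NAMES = ["Alice", "Bruno", "Carla", "Diego", "Elena", "Fatima", "Goran", "Hana",
                "Ivan", "Julia", "Kenji", "Lena", "Marta", "Nils", "Olga", "Pavel"]
_LAST_NAMES = ["Moreau", "Schmidt", "Rossi", "Novak", "Berg", "Costa", "Dubois", "Weber"]

# scripted acts for the first patient, guaranteeing that every suite query
# returns at least one solution on the default fixture
_INDEX_CASE = [
    ("observation", "ANEMIA", "Anemia finding", "completed",
     dict(value=10.5, valueUnit="g/dL", referenceRangeMin=12.0, referenceRangeMax=16.0,
          interpretationCode="L", methodCode="M1", targetSiteCode="TS1")),
    ("observation", "WEIGHT", "Body weight", "completed",
     dict(value=65.0, valueUnit="kg", referenceRangeMin=None, referenceRangeMax=None,
          interpretationCode="N", methodCode=None, targetSiteCode=None)),
    ("observation", "HEIGHT", "Body height", "completed",
     dict(value=1.7, valueUnit="m", referenceRangeMin=None, referenceRangeMax=None,
          interpretationCode=None, methodCode=None, targetSiteCode=None)),
    ("observation", "TUMOR-T2", "Tumor stage T2", "active",
     dict(value=2.1, valueUnit="cm", referenceRangeMin=1.0, referenceRangeMax=3.0,
          interpretationCode="H", methodCode="M2", targetSiteCode="TS2")),
    ("procedure", "CHEMO-1", "Chemotherapy course", "completed",
     dict(methodCode="M1", targetSiteCode="TS1", approachSiteCode="AS1")),
    ("substance_administration", "DIPHOS", "Diphosphonate administration", "completed",
     dict(doseQuantity=70.0, routeCode="PO", methodCode="M1",
          targetSiteCode="TS1", approachSiteCode="AS1")),
    ("observation", "GLUCOSE", "Glucose measurement", "completed",
     dict(value=5.4, valueUnit="mmol/L", referenceRangeMin=3.9, referenceRangeMax=5.6,
          interpretationCode="N", methodCode=None, targetSiteCode=None)),
    ("exposure", "ENV", "Environmental exposure", None, dict(typeCode="ENV")),
]

_ACT_CLASS = {
    "observation": "OBS",
    "procedure": "PROC",
    "substance_administration": "SBADM",
    "exposure": "EXPOS",
}


def _maybe(rng: random.Random, rate: float, value):
    return None if rng.random() < rate else value


def populate(config: FixtureConfig, connection: sqlite3.Connection) -> Dict[str, int]:
    """Fill the schema deterministically under the configured seed.

    Acts are dealt to patients round-robin (``n_acts == n_patients`` gives
    every patient exactly one act); the first patient's acts are scripted
    so the representative queries are all satisfiable, the rest are random
    draws with ``null_rate`` of the nullable attributes NULL.
    """
    rng = random.Random(config.seed)
    cur = connection.cursor()

    for table, rows in (
        ("act_method_code", _METHODS),
        ("act_target_site_code", _TARGET_SITES),
        ("act_approach_site_code", _APPROACH_SITES),
        ("act_observation_interpretation_code", _INTERPRETATIONS),
        ("act_observation_values", _OBS_VALUE_CODES),
    ):
        ph = ", ".join("?" * len(rows[0]))
        cur.executemany(f'INSERT INTO "{table}" VALUES ({ph})', rows)

    counts = {k: 0 for k in _ACT_CLASS}
    base_date = datetime.date(2014, 1, 1)

    for i in range(1, config.n_patients + 1):
        pid = f"P-{i:04d}"
        eid = f"E-{i:04d}"
        if i == 1:
            name, gender = "Alice Index", "F"
            birth = "1970-05-12"
            marital = "M"
        else:
            name = _maybe(
                rng, config.null_rate,
                f"{rng.choice(_FIRST_NAMES)} {rng.choice(_LAST_NAMES)}",
            )
            gender = rng.choice(["F", "F", "M"])  # breast-cancer cohort skew
            birth = (
                datetime.date(1935, 1, 1)
                + datetime.timedelta(days=rng.randrange(0, 65 * 365))
            ).isoformat()
            marital = _maybe(rng, config.null_rate, rng.choice(["S", "M", "D", "W"]))
        cur.execute("INSERT INTO entity VALUES (?,?,?)", (eid, "PSN", "INSTANCE"))
        cur.execute(
            "INSERT INTO person VALUES (?,?,?,?,?,?)",
            (eid, pid, name, gender, birth, marital),
        )
        cur.execute(
            "INSERT INTO role VALUES (?,?,?)", (f"R-{i:04d}", eid, "PAT")
        )

    per_patient_seen = [0] * (config.n_patients + 1)
    for i in range(1, config.n_acts + 1):
        patient = (i - 1) % config.n_patients + 1
        per_patient_seen[patient] += 1
        aid = f"A-{i:05d}"
        scripted = (
            patient == 1 and per_patient_seen[1] <= len(_INDEX_CASE)
        )
        if scripted:
            kind, code, title, status, extra = _INDEX_CASE[per_patient_seen[1] - 1]
            eff = (base_date + datetime.timedelta(days=30 * per_patient_seen[1])).isoformat()
        else:
            kind = rng.choices(
                ["observation", "procedure", "substance_administration", "exposure"],
                weights=[55, 20, 15, 10],
            )[0]
            if kind == "observation":
                code = rng.choice(_OBS_CODES)
            elif kind == "procedure":
                code = rng.choice(_PROC_CODES)
            elif kind == "substance_administration":
                code = rng.choices(_SA_CODES, weights=_SA_WEIGHTS)[0]
            else:
                code = rng.choice(_EXPOSURE_CODES)
            title = _maybe(rng, config.null_rate, f"{code.title()} record")
            status = _maybe(rng, config.null_rate, rng.choice(["completed", "active"]))
            eff = (
                base_date + datetime.timedelta(days=rng.randrange(0, 3 * 365))
            ).isoformat()
            extra = None
        counts[kind] += 1
        cur.execute(
            "INSERT INTO act VALUES (?,?,?,?,?,?,?)",
            (aid, _ACT_CLASS[kind], "EVN", code, title, eff, status),
        )
        cur.execute(
            "INSERT INTO participation VALUES (?,?,?,?)",
            (f"PT-{i:05d}", aid, f"R-{patient:04d}", "SBJ"),
        )
        if kind == "observation":
            if extra is None:
                ref_present = rng.random() >= config.null_rate
                extra = dict(
                    value=_maybe(rng, config.null_rate, round(rng.uniform(0.5, 200.0), 2)),
                    valueUnit=_maybe(rng, config.null_rate, rng.choice(["kg", "m", "mmol/L", "g/dL", "cm"])),
                    referenceRangeMin=round(rng.uniform(0.5, 50.0), 2) if ref_present else None,
                    referenceRangeMax=round(rng.uniform(50.0, 200.0), 2) if ref_present else None,
                    interpretationCode=_maybe(rng, config.null_rate, rng.choice(["L", "N", "H"])),
                    methodCode=_maybe(rng, config.null_rate, rng.choice([m[0] for m in _METHODS])),
                    targetSiteCode=_maybe(rng, config.null_rate, rng.choice([t[0] for t in _TARGET_SITES])),
                )
                if code == "WEIGHT" and extra["value"] is not None:
                    extra["value"] = round(rng.uniform(45.0, 110.0), 2)
                    extra["valueUnit"] = "kg"
                if code == "HEIGHT" and extra["value"] is not None:
                    extra["value"] = round(rng.uniform(1.45, 1.95), 2)
                    extra["valueUnit"] = "m"
            cur.execute(
                "INSERT INTO observation VALUES (?,?,?,?,?,?,?,?)",
                (aid, extra["value"], extra["valueUnit"], extra["referenceRangeMin"],
                 extra["referenceRangeMax"], extra["interpretationCode"],
                 extra["methodCode"], extra["targetSiteCode"]),
            )
        elif kind == "procedure":
            if extra is None:
                extra = dict(
                    methodCode=_maybe(rng, config.null_rate, rng.choice([m[0] for m in _METHODS])),
                    targetSiteCode=_maybe(rng, config.null_rate, rng.choice([t[0] for t in _TARGET_SITES])),
                    approachSiteCode=_maybe(rng, config.null_rate, rng.choice([a[0] for a in _APPROACH_SITES])),
                )
            cur.execute(
                'INSERT INTO "procedure" VALUES (?,?,?,?)',
                (aid, extra["methodCode"], extra["targetSiteCode"], extra["approachSiteCode"]),
            )
        elif kind == "substance_administration":
            if extra is None:
                extra = dict(
                    doseQuantity=_maybe(rng, config.null_rate, round(rng.uniform(5.0, 500.0), 2)),
                    routeCode=_maybe(rng, config.null_rate, rng.choice(["PO", "IV", "IM", "SC"])),
                    methodCode=_maybe(rng, config.null_rate, rng.choice([m[0] for m in _METHODS])),
                    targetSiteCode=_maybe(rng, config.null_rate, rng.choice([t[0] for t in _TARGET_SITES])),
                    approachSiteCode=_maybe(rng, config.null_rate, rng.choice([a[0] for a in _APPROACH_SITES])),
                )
            cur.execute(
                "INSERT INTO substance_administration VALUES (?,?,?,?,?,?)",
                (aid, extra["doseQuantity"], extra["routeCode"], extra["methodCode"],
                 extra["targetSiteCode"], extra["approachSiteCode"]),
            )
        else:
            type_code = extra["typeCode"] if extra else _maybe(
                rng, config.null_rate, rng.choice(_EXPOSURE_CODES)
            )
            cur.execute("INSERT INTO exposure VALUES (?,?)", (aid, type_code))

    connection.commit()
    return {
        "patients": config.n_patients,
        "acts": config.n_acts,
        "observations": counts["observation"],
        "procedures": counts["procedure"],
        "substance_administrations": counts["substance_administration"],
        "exposures": counts["exposure"],
    }


# --------------------------------------------------------------------------
# mapping document emission


def _tm(tm_id: str, table: str, subject_template: str, cls: str,
        columns: List[Tuple[str, str, Optional[str]]],
        refs: List[Tuple[str, str, str, str]],
        templates: Optional[List[Tuple[str, str]]] = None) -> str:
    lines = [f"<#{tm_id}>"]
    lines.append(f'    rr:logicalTable [ rr:tableName "{table}" ] ;')
    lines.append(
        f'    rr:subjectMap [ rr:template "{subject_template}" ; rr:class :{cls} ] ;'
    )
    poms = []
    for prop, col, datatype in columns:
        om = f'rr:column "{col}"'
        if datatype:
            om += f" ; rr:datatype xsd:{datatype}"
        poms.append(
            f"    rr:predicateObjectMap [ rr:predicate :{prop} ;"
            f" rr:objectMap [ {om} ] ]"
        )
    for tpl_prop, tpl in templates or []:
        poms.append(
            f"    rr:predicateObjectMap [ rr:predicate :{tpl_prop} ;"
            f' rr:objectMap [ rr:template "{tpl}" ; rr:termType rr:Literal ] ]'
        )
    for prop, parent, child_col, parent_col in refs:
        poms.append(
            f"    rr:predicateObjectMap [ rr:predicate :{prop} ;"
            f" rr:objectMap [ rr:parentTriplesMap <#{parent}> ;"
            f' rr:joinCondition [ rr:child "{child_col}" ; rr:parent "{parent_col}" ] ] ]'
        )
    return "\n".join(lines) + " ;\n" + " ;\n".join(poms) + " .\n"


def emit_mappings() -> str:
    """The fixture's R2RML mapping document (Turtle)."""
    header = (
        "@prefix rr: <http://www.w3.org/ns/r2rml#> .\n"
        f"@prefix : <{ONT}> .\n"
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .\n\n"
    )
    parts = [header]
    # step 2: tables with a context view are mapped through the view
    parts.append(_tm(
        "TMap_v_person", "v_person", RES + "Patient/{patientId}", "Patient",
        [("person_id", "patientId", None),
         ("person_name", "patientName", None),
         ("person_gender", "gender", None),
         ("person_birthTime", "birthTime", "date")],
        [("person_observation", "TMap_v_observation", "patientId", "patientId"),
         ("person_procedure", "TMap_v_procedure", "patientId", "patientId"),
         ("person_substanceAdministration", "TMap_v_substanceadministration",
          "patientId", "patientId")],
    ))
    parts.append(_tm(
        "TMap_v_observation", "v_observation", RES + "Observation/{actId}",
        "Observation",
        [("observation_code", "code", None),
         ("observation_title", "title", None),
         ("observation_effectiveTime", "effectiveTime", "date"),
         ("observation_status", "statusCode", None),
         ("observation_value", "value", "decimal"),
         ("observation_valueUnit", "valueUnit", None)],
        [("observation_method", "TMap_act_method_code", "methodCode", "code"),
         ("observation_targetSite", "TMap_act_target_site_code", "targetSiteCode", "code"),
         ("observation_interpretation", "TMap_act_observation_interpretation_code",
          "interpretationCode", "code")],
        templates=[("observation_refRange", "{referenceRangeMin} - {referenceRangeMax}")],
    ))
    parts.append(_tm(
        "TMap_v_procedure", "v_procedure", RES + "Procedure/{actId}", "Procedure",
        [("procedure_code", "code", None),
         ("procedure_title", "title", None),
         ("procedure_effectiveTime", "effectiveTime", "date"),
         ("procedure_status", "statusCode", None)],
        [("procedure_method", "TMap_act_method_code", "methodCode", "code"),
         ("procedure_targetSite", "TMap_act_target_site_code", "targetSiteCode", "code"),
         ("procedure_approachSite", "TMap_act_approach_site_code", "approachSiteCode", "code")],
    ))
    parts.append(_tm(
        "TMap_v_substanceadministration", "v_substanceadministration",
        RES + "SubstanceAdministration/{actId}", "SubstanceAdministration",
        [("sa_code", "code", None),
         ("sa_title", "title", None),
         ("sa_effectiveTime", "effectiveTime", "date"),
         ("sa_status", "statusCode", None),
         ("sa_doseQuantity", "doseQuantity", "decimal"),
         ("sa_routeCode", "routeCode", None)],
        [("sa_method", "TMap_act_method_code", "methodCode", "code"),
         ("sa_targetSite", "TMap_act_target_site_code", "targetSiteCode", "code"),
         ("sa_approachSite", "TMap_act_approach_site_code", "approachSiteCode", "code")],
    ))
    # step 1: remaining base tables, direct-mapping style
    parts.append(_tm(
        "TMap_act", "act", RES + "Act/{actId}", "Act",
        [("act_classCode", "classCode", None),
         ("act_moodCode", "moodCode", None),
         ("act_code", "code", None),
         ("act_title", "title", None),
         ("act_effectiveTime", "effectiveTime", "date"),
         ("act_statusCode", "statusCode", None)],
        [("act_observation", "TMap_v_observation", "actId", "actId"),
         ("act_procedure", "TMap_v_procedure", "actId", "actId"),
         ("act_substanceAdministration", "TMap_v_substanceadministration", "actId", "actId"),
         ("act_exposure", "TMap_exposure", "actId", "actId")],
    ))
    parts.append(_tm(
        "TMap_exposure", "exposure", RES + "Exposure/{actId}", "Exposure",
        [("exposure_typeCode", "typeCode", None)],
        [],
    ))
    parts.append(_tm(
        "TMap_entity", "entity", RES + "Entity/{entityId}", "Entity",
        [("entity_classCode", "classCode", None),
         ("entity_determinerCode", "determinerCode", None)],
        [],
    ))
    parts.append(_tm(
        "TMap_role", "role", RES + "Role/{roleId}", "Role",
        [("role_classCode", "classCode", None)],
        [("role_player", "TMap_entity", "entityId", "entityId")],
    ))
    parts.append(_tm(
        "TMap_participation", "participation", RES + "Participation/{participationId}",
        "Participation",
        [("participation_typeCode", "typeCode", None)],
        [("participation_act", "TMap_act", "actId", "actId"),
         ("participation_role", "TMap_role", "roleId", "roleId")],
    ))
    parts.append(_tm(
        "TMap_act_method_code", "act_method_code", RES + "MethodCode/{code}",
        "ActMethodCode",
        [("method_name", "name", None), ("method_description", "description", None)],
        [],
    ))
    parts.append(_tm(
        "TMap_act_target_site_code", "act_target_site_code",
        RES + "TargetSiteCode/{code}", "ActTargetSiteCode",
        [("targetSite_name", "name", None), ("targetSite_description", "description", None)],
        [],
    ))
    parts.append(_tm(
        "TMap_act_approach_site_code", "act_approach_site_code",
        RES + "ApproachSiteCode/{code}", "ActApproachSiteCode",
        [("approachSite_name", "name", None), ("approachSite_description", "description", None)],
        [],
    ))
    parts.append(_tm(
        "TMap_act_observation_interpretation_code",
        "act_observation_interpretation_code",
        RES + "InterpretationCode/{code}", "ActObservationInterpretationCode",
        [("interpretation_name", "name", None)],
        [],
    ))
    parts.append(_tm(
        "TMap_act_observation_values", "act_observation_values",
        RES + "ObservationValue/{code}", "ActObservationValue",
        [("observationValue_label", "label", None)],
        [],
    ))
    return "\n".join(parts)


# --------------------------------------------------------------------------
# query suite

_PREFIX = f"PREFIX : <{ONT}>\n"

_Q01 = _PREFIX + """\
# Demographics: female patients with an observation; the observation title
# may be missing.
SELECT ?p ?gender ?o ?title WHERE {
  ?p a :Patient .
  ?p :person_gender ?gender .
  ?p :person_observation ?o .
  OPTIONAL { ?o :observation_title ?title }
  FILTER (?gender = "F")
}
"""

_Q10 = _PREFIX + """\
# Substance administration: patients administered diphosphonate, with the
# method, target site and approach site, and all clinical detail attached
# where it exists.
SELECT ?p ?id ?sa ?mname ?tsname ?asname ?obs ?ocode ?pname ?birth ?stitle
       ?dose ?route ?sstatus ?mdesc ?tsdesc ?asdesc ?otitle ?ovalue ?ounit
       ?orange ?otime ?ostatus ?interp ?iname ?proc ?ptitle ?pm ?pmdesc
WHERE {
  ?p a :Patient .
  ?p :person_id ?id .
  ?p :person_gender ?gender .
  ?p :person_substanceAdministration ?sa .
  ?sa :sa_code ?scode .
  ?sa :sa_effectiveTime ?stime .
  ?sa :sa_method ?m .
  ?m :method_name ?mname .
  ?sa :sa_targetSite ?ts .
  ?ts :targetSite_name ?tsname .
  ?sa :sa_approachSite ?as .
  ?as :approachSite_name ?asname .
  ?p :person_observation ?obs .
  ?obs :observation_code ?ocode .
  OPTIONAL { ?p :person_name ?pname }
  OPTIONAL { ?p :person_birthTime ?birth }
  OPTIONAL { ?sa :sa_title ?stitle }
  OPTIONAL { ?sa :sa_doseQuantity ?dose }
  OPTIONAL { ?sa :sa_routeCode ?route }
  OPTIONAL { ?sa :sa_status ?sstatus }
  OPTIONAL { ?m :method_description ?mdesc }
  OPTIONAL { ?ts :targetSite_description ?tsdesc }
  OPTIONAL { ?as :approachSite_description ?asdesc }
  OPTIONAL { ?obs :observation_title ?otitle }
  OPTIONAL { ?obs :observation_value ?ovalue }
  OPTIONAL { ?obs :observation_valueUnit ?ounit }
  OPTIONAL { ?obs :observation_refRange ?orange }
  OPTIONAL { ?obs :observation_effectiveTime ?otime }
  OPTIONAL { ?obs :observation_status ?ostatus }
  OPTIONAL { ?obs :observation_interpretation ?interp
             OPTIONAL { ?interp :interpretation_name ?iname } }
  OPTIONAL { ?p :person_procedure ?proc
             OPTIONAL { ?proc :procedure_title ?ptitle }
             OPTIONAL { ?proc :procedure_method ?pm
                        OPTIONAL { ?pm :method_description ?pmdesc } } }
  FILTER (?scode IN ("DIPHOS"))
}
"""

_Q14 = _PREFIX + """\
# Laboratory results: anemia patients whose body mass index
# (weight / height^2) is at most 30.
SELECT ?p ?id ?anemia ?acode ?wv ?hv ?atitle ?meth ?mname ?site ?sname
WHERE {
  ?p a :Patient .
  ?p :person_id ?id .
  ?p :person_observation ?anemia .
  ?anemia :observation_code ?acode .
  ?p :person_observation ?wobs .
  ?wobs :observation_code "WEIGHT" .
  ?wobs :observation_value ?wv .
  ?p :person_observation ?hobs .
  ?hobs :observation_code "HEIGHT" .
  ?hobs :observation_value ?hv .
  OPTIONAL { ?anemia :observation_title ?atitle }
  OPTIONAL { ?anemia :observation_method ?meth
             OPTIONAL { ?meth :method_name ?mname } }
  OPTIONAL { ?anemia :observation_targetSite ?site
             OPTIONAL { ?site :targetSite_name ?sname } }
  FILTER (?acode IN ("ANEMIA"))
  FILTER (?wv / (?hv * ?hv) <= 30)
}
"""

_Q34 = _PREFIX + """\
# Procedure: patients administered chemotherapy, with the method used and
# its description where recorded.
SELECT ?p ?id ?proc ?code ?m ?mdesc WHERE {
  ?p a :Patient .
  ?p :person_id ?id .
  ?p :person_procedure ?proc .
  ?proc :procedure_code ?code .
  ?proc :procedure_method ?m .
  OPTIONAL { ?m :method_description ?mdesc }
  FILTER (?code IN ("CHEMO-1", "CHEMO-2"))
}
"""

_Q45 = _PREFIX + """\
# Observation: non-male patients with a category T2 breast tumor finding,
# its target site, and any procedure, with optional detail.
SELECT ?p ?id ?gender ?tumor ?tv ?sname ?proc ?pcode ?ttitle ?range ?meth ?mname
WHERE {
  ?p a :Patient .
  ?p :person_id ?id .
  ?p :person_gender ?gender .
  ?p :person_observation ?tumor .
  ?tumor :observation_code ?tcode .
  ?tumor :observation_value ?tv .
  ?tumor :observation_targetSite ?site .
  ?site :targetSite_name ?sname .
  ?p :person_procedure ?proc .
  ?proc :procedure_code ?pcode .
  OPTIONAL { ?tumor :observation_title ?ttitle }
  OPTIONAL { ?tumor :observation_refRange ?range }
  OPTIONAL { ?proc :procedure_method ?meth
             OPTIONAL { ?meth :method_name ?mname } }
  FILTER (?tcode IN ("TUMOR-T2"))
  FILTER (?gender != "M")
}
"""

_Q_ANY = _PREFIX + """\
# Auxiliary unbound-predicate probe: every property whose value is the
# literal "F" (exercises union translation and union reduction).
SELECT ?pt ?prop WHERE {
  ?pt ?prop "F" .
}
"""

#: representative query shapes: (triple patterns, unique subjects,
#: OPTIONAL blocks, FILTER patterns)
QUERY_SHAPES: Dict[str, Tuple[int, int, int, int]] = {
    "q01": (4, 2, 1, 1),
    "q10": (35, 9, 21, 1),
    "q14": (15, 6, 5, 2),
    "q34": (6, 3, 1, 1),
    "q45": (14, 5, 4, 2),
}

_QUERIES: Dict[str, str] = {
    "q01": _Q01,
    "q10": _Q10,
    "q14": _Q14,
    "q34": _Q34,
    "q45": _Q45,
    "q_any": _Q_ANY,
}


def emit_query_suite(out_dir: Path) -> Dict[str, Path]:
    """Write the five representative queries plus the auxiliary
    unbound-predicate query to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, text in _QUERIES.items():
        p = out_dir / f"{name}.rq"
        p.write_text(text)
        paths[name] = p
    return paths


def query_text(name: str) -> str:
    return _QUERIES[name]


# --------------------------------------------------------------------------
# independent triple counting (manifest oracle)


def expected_triple_count(
    connection: sqlite3.Connection, mapping: Optional[MappingDocument] = None
) -> int:
    """Count the triples an R2RML materialization must produce, by direct
    SQL row enumeration per term map (NULL-aware, duplicate-free).  This is
    deliberately independent of the materializer's own code path."""
    from .r2rml_mappings import RefObjectMap, referenced_columns

    if mapping is None:
        mapping = parse_mapping(emit_mappings())
    cur = connection.cursor()
    total = 0

    def q(name: str) -> str:
        return '"' + name.replace('"', '""') + '"'

    for tm in mapping.triples_maps:
        subj_cols = list(referenced_columns(tm.subject_map))
        notnull_subj = " AND ".join(f"{q(c)} IS NOT NULL" for c in subj_cols) or "1=1"
        subj_sel = ", ".join(q(c) for c in subj_cols)
        n_subjects = cur.execute(
            f"SELECT COUNT(*) FROM (SELECT DISTINCT {subj_sel} FROM {q(tm.table)}"
            f" WHERE {notnull_subj})"
        ).fetchone()[0]
        total += n_subjects * len(tm.class_iris)
        for pom in tm.predicate_object_maps:
            if isinstance(pom.object_map, RefObjectMap):
                rom = pom.object_map
                parent = mapping.get(rom.parent_triples_map)
                p_cols = list(referenced_columns(parent.subject_map))
                sel = ", ".join(
                    [f"c.{q(c)}" for c in subj_cols] + [f"p.{q(c)}" for c in p_cols]
                )
                on = " AND ".join(
                    f"c.{q(cc)} = p.{q(pc)}" for cc, pc in rom.join_conditions
                )
                wh = " AND ".join(
                    [f"c.{q(c)} IS NOT NULL" for c in subj_cols]
                    + [f"p.{q(c)} IS NOT NULL" for c in p_cols]
                ) or "1=1"
                total += cur.execute(
                    f"SELECT COUNT(*) FROM (SELECT DISTINCT {sel}"
                    f" FROM {q(tm.table)} c JOIN {q(parent.table)} p ON {on}"
                    f" WHERE {wh})"
                ).fetchone()[0]
            else:
                obj_cols = list(referenced_columns(pom.object_map))
                cols = list(dict.fromkeys(subj_cols + obj_cols))
                wh = " AND ".join(f"{q(c)} IS NOT NULL" for c in cols) or "1=1"
                sel = ", ".join(q(c) for c in cols)
                total += cur.execute(
                    f"SELECT COUNT(*) FROM (SELECT DISTINCT {sel} FROM {q(tm.table)}"
                    f" WHERE {wh})"
                ).fetchone()[0]
    return total


# --------------------------------------------------------------------------
# bundle


def build_bundle(config: FixtureConfig) -> FixtureBundle:
    """Generate the full fixture bundle: database file, mapping document,
    query files, and a manifest recording the expected query shapes and
    the independently counted materialized-triple total."""
    out_dir = Path(config.out_dir or "fixtures")
    out_dir.mkdir(parents=True, exist_ok=True)
    db_path = out_dir / "fixture.db"
    if db_path.exists():
        db_path.unlink()
    conn = sqlite3.connect(db_path)
    try:
        build_schema(conn)
        counts = populate(config, conn)
        mapping_text = emit_mappings()
        mapping_path = out_dir / "mappings.ttl"
        mapping_path.write_text(mapping_text)
        query_paths = emit_query_suite(out_dir)
        triple_count = expected_triple_count(conn)
    finally:
        conn.close()
    manifest = {
        "config": {
            "seed": config.seed,
            "n_patients": config.n_patients,
            "n_acts": config.n_acts,
            "null_rate": config.null_rate,
        },
        "counts": counts,
        "expected_triples": triple_count,
        "queries": {
            name: {
                "file": query_paths[name].name,
                "shape": list(QUERY_SHAPES[name]) if name in QUERY_SHAPES else None,
                "representative": name in QUERY_SHAPES,
            }
            for name in _QUERIES
        },
        # the printed grouping table is ambiguous about the demographics
        # query's FILTER column; the prose description (one FILTER) wins
        "notes": "q01 carries 1 FILTER per its prose description",
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return FixtureBundle(
        db_path=db_path,
        mapping_path=mapping_path,
        query_paths=query_paths,
        manifest=manifest,
        manifest_path=manifest_path,
    )


# --------------------------------------------------------------------------
# the two-table worked example (patients and observations)

#: Synthetic reconstruction of the two-table worked example: a patient
#: view with an observation link.  Used by unit tests and documentation.
EXAMPLE_MAPPING_TTL = """\
@prefix rr: <http://www.w3.org/ns/r2rml#> .
@prefix : <http://example.org/> .

<#TMapPerson>
    rr:logicalTable [ rr:tableName "v_person" ] ;
    rr:subjectMap [ rr:template "http://example.org/Patient/{patientId}" ;
                    rr:class :Patient ] ;
    rr:predicateObjectMap [ rr:predicate :hasPatientID ;
                            rr:objectMap [ rr:column "patientId" ] ] ;
    rr:predicateObjectMap [ rr:predicate :hasPatientName ;
                            rr:objectMap [ rr:column "patientName" ] ] ;
    rr:predicateObjectMap [ rr:predicate :hasObservation ;
        rr:objectMap [ rr:parentTriplesMap <#TMapObservation> ;
                       rr:joinCondition [ rr:child "actId" ;
                                          rr:parent "actId" ] ] ] .

<#TMapObservation>
    rr:logicalTable [ rr:tableName "v_observation" ] ;
    rr:subjectMap [ rr:template "http://example.org/Observation/{actId}" ;
                    rr:class :Observation ] ;
    rr:predicateObjectMap [ rr:predicate :hasTitle ;
                            rr:objectMap [ rr:column "title" ] ] .
"""

#: Reduced variant with exactly one literal-range and one IRI-range
#: predicate map, the union-reduction demonstration setup.
EXAMPLE6_MAPPING_TTL = """\
@prefix rr: <http://www.w3.org/ns/r2rml#> .
@prefix : <http://example.org/> .

<#TMapPerson>
    rr:logicalTable [ rr:tableName "v_person" ] ;
    rr:subjectMap [ rr:template "http://example.org/Patient/{patientId}" ] ;
    rr:predicateObjectMap [ rr:predicate :hasPatientName ;
                            rr:objectMap [ rr:column "patientName" ] ] ;
    rr:predicateObjectMap [ rr:predicate :hasObservation ;
        rr:objectMap [ rr:parentTriplesMap <#TMapObservation> ;
                       rr:joinCondition [ rr:child "actId" ;
                                          rr:parent "actId" ] ] ] .

<#TMapObservation>
    rr:logicalTable [ rr:tableName "v_observation" ] ;
    rr:subjectMap [ rr:template "http://example.org/Observation/{actId}" ] ;
    rr:predicateObjectMap [ rr:predicate :hasTitle ;
                            rr:objectMap [ rr:column "title" ] ] .
"""


def build_example_database(connection: sqlite3.Connection) -> None:
    """Two toy tables (synthetic stand-in for the worked example's printed
    instances): three patients, three observations, one NULL name and one
    NULL title to exercise the R2RML NULL rule."""
    cur = connection.cursor()
    cur.executescript(
        """
        CREATE TABLE v_person (
            patientId TEXT PRIMARY KEY,
            patientName TEXT,
            gender TEXT,
            actId TEXT
        );
        CREATE TABLE v_observation (
            actId TEXT PRIMARY KEY,
            title TEXT,
            code TEXT
        );
        """
    )
    cur.executemany(
        "INSERT INTO v_person VALUES (?,?,?,?)",
        [
            ("1", "Bob", "M", "A1"),
            ("2", "Alice", "F", "A2"),
            ("3", None, "F", "A3"),
        ],
    )
    cur.executemany(
        "INSERT INTO v_observation VALUES (?,?,?)",
        [
            ("A1", "Blood pressure", "BP"),
            ("A2", "Body weight", "WEIGHT"),
            ("A3", None, "GLUCOSE"),
        ],
    )
    connection.commit()
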