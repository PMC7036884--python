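"""Readers and writers for every external artifact.

Two groups of functionality live here:

* **Bundled fixtures** — the transcribed school-enrollment table (26
  municipal schools with health territory and 2017 enrollment counts)
  and the two questionnaire structures (student: 146 questions in 12
  classes; principal: 84 questions).  Fixture files are SHA-256
  checksummed; an edited transcription fails loudly.

* **Store export / import** — the central store serialized to CSV, XML
  or JSON for external analysis tools, with a lossless round trip.
  Exams are flattened in two layouts: *per-tooth long* (one row per
  tooth) and *per-exam wide* (one column per tooth); questionnaire
  responses are exported wide (one column per question).  The CSV
  dialect is fixed: UTF-8, comma separators, quoted strings, ISO dates.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable, Literal, Optional

from lxml import etree

from .model import (
    QuestionnaireDef,
    School,
    SurveyValidationError,
)
from .sync import ENTITY_TYPES, CentralStore, canonical_json

DATA_DIR = Path(__file__).parent / "data"

#: SHA-256 of each bundled fixture file; transcriptions are frozen.
FIXTURE_CHECKSUMS = {
    "palmas_schools_2017.json":
        "03d3252e4e591bc42a171875280d98885d145312a1bc9710d806151b690ec6e7",
    "student_questionnaire.json":
        "a9302caa9dab5b554fe6517c3f6e2fd13b35e827952cba583e36218c937d9fe0",
    "principal_questionnaire.json":
        "2b52e85b88e58d3fbe5464292fe40e7cf6d8e43cbd34d66d12460a57832919fd",
}

ExamLayout = Literal["per_tooth", "per_exam"]
Format = Literal["csv", "xml", "json"]


def _load_fixture(name: str) -> dict:
    path = DATA_DIR / name
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_CHECKSUMS[name]:
        raise SurveyValidationError(
            f"fixture {name} checksum mismatch: transcription was edited "
            f"(got {digest})"
        )
    return json.loads(raw.decode("utf-8"))


def load_school_enrollment() -> list[School]:
    """The transcribed municipal school list: territory and 2017
    enrollment (total and 9th grade) per school."""
    doc = _load_fixture("palmas_schools_2017.json")
    return [School.model_validate(s) for s in doc["schools"]]


def school_enrollment_printed_totals() -> tuple[int, int]:
    """The municipal totals as printed with the source table."""
    doc = _load_fixture("palmas_schools_2017.json")
    totals = doc["printed_totals"]
    return totals["enrollment_total"], totals["enrollment_grade9"]


def school_territory_mapping() -> dict[str, str]:
    """Explicit school-id -> health-territory mapping from the fixture."""
    return {s.id: s.territory for s in load_school_enrollment()}


def load_student_questionnaire() -> QuestionnaireDef:
    """The 146-question student questionnaire structure (12 classes)."""
    doc = _load_fixture("student_questionnaire.json")
    return QuestionnaireDef(name=doc["name"], classes=doc["classes"])


def load_principal_questionnaire() -> QuestionnaireDef:
    """The 84-question school-principal questionnaire structure."""
    doc = _load_fixture("principal_questionnaire.json")
    return QuestionnaireDef(name=doc["name"], classes=doc["classes"])


# ---------------------------------------------------------------------------
# Flattening helpers (records <-> rows)
# ---------------------------------------------------------------------------

_META_COLS = ("record_uid", "created_at", "schema_version")


def _meta(record: dict) -> dict:
    return {k: record[k] for k in _META_COLS}


def _exam_rows_per_tooth(record: dict) -> list[dict]:
    payload = record["payload"]
    teeth = payload["odontogram"]["teeth"]
    rows = []
    for tooth_str, rec in sorted(
        payload["odontogram"]["records"].items(), key=lambda kv: int(kv[0])
    ):
        rows.append(
            {
                **_meta(record),
                "secret_code": payload["secret_code"],
                "date": payload["date"],
                "examiner_id": payload["examiner_id"],
                "annotator_id": payload["annotator_id"],
                "teeth": " ".join(str(t) for t in teeth),
                "tooth": rec["tooth"],
                "crown": rec["crown"],
                "treatment": rec["treatment"],
            }
        )
    return rows


def _exam_row_wide(record: dict, all_teeth: list[int]) -> dict:
    payload = record["payload"]
    teeth = payload["odontogram"]["teeth"]
    row = {
        **_meta(record),
        "secret_code": payload["secret_code"],
        "date": payload["date"],
        "examiner_id": payload["examiner_id"],
        "annotator_id": payload["annotator_id"],
        "teeth": " ".join(str(t) for t in teeth),
    }
    recs = payload["odontogram"]["records"]
    for t in all_teeth:
        rec = recs.get(str(t))
        # crown and treatment are single symbols: concatenation is unambiguous
        row[f"t{t}"] = f"{rec['crown']}{rec['treatment']}" if rec else ""
    return row


def _exam_payload_from_tooth_rows(rows: list[dict]) -> dict:
    first = rows[0]
    records = {}
    for row in rows:
        records[str(row["tooth"])] = {
            "tooth": int(row["tooth"]),
            "crown": row["crown"],
            "treatment": row["treatment"],
        }
    return {
        "secret_code": first["secret_code"],
        "date": first["date"],
        "examiner_id": first["examiner_id"],
        "annotator_id": first["annotator_id"],
        "odontogram": {
            "teeth": [int(t) for t in first["teeth"].split()],
            "records": records,
        },
    }


def _exam_payload_from_wide_row(row: dict) -> dict:
    records = {}
    for key, value in row.items():
        if key.startswith("t") and key[1:].isdigit() and value:
            tooth = int(key[1:])
            records[str(tooth)] = {
                "tooth": tooth,
                "crown": value[0],
                "treatment": value[1],
            }
    return {
        "secret_code": row["secret_code"],
        "date": row["date"],
        "examiner_id": row["examiner_id"],
        "annotator_id": row["annotator_id"],
        "odontogram": {
            "teeth": [int(t) for t in row["teeth"].split()],
            "records": records,
        },
    }


def _flat_rows(record: dict, kind: str) -> dict:
    payload = dict(record["payload"])
    if kind == "action":
        payload["school_ids"] = ";".join(payload.get("school_ids", []))
    if kind == "response":
        answers = payload.pop("answers", {})
        for q, a in sorted(answers.items(), key=lambda kv: int(kv[0])):
            payload[f"q{q}"] = a
    if kind == "school":
        for col in ("latitude", "longitude", "territory"):
            if payload.get(col) is None:
                payload[col] = ""
    return {**_meta(record), **payload}


def _payload_from_flat(row: dict, kind: str) -> dict:
    payload = {k: v for k, v in row.items() if k not in _META_COLS}
    if kind == "action":
        ids = payload.get("school_ids", "")
        payload["school_ids"] = ids.split(";") if ids else []
    if kind == "response":
        answers = {}
        for key in list(payload):
            if key.startswith("q") and key[1:].isdigit():
                value = payload.pop(key)
                if value != "":
                    answers[key[1:]] = value
        payload["answers"] = answers
    if kind == "school":
        for col in ("latitude", "longitude", "territory"):
            if payload.get(col) == "":
                payload[col] = None
    return payload


def _normalize(kind: str, payload: dict) -> dict:
    """Re-validate through the entity model so typed fields (ints, dates,
    floats) come back exactly as originally serialized."""
    return ENTITY_TYPES[kind].model_validate(payload).model_dump(mode="json")


def _rebuild_record(kind: str, meta: dict, payload: dict) -> dict:
    return {
        "record_uid": meta["record_uid"],
        "kind": kind,
        "created_at": meta["created_at"],
        "schema_version": meta["schema_version"],
        "payload": _normalize(kind, payload),
    }


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _write_csv(path: Path, rows: list[dict]) -> None:
    fieldnames: list[str] = []
    for row in rows:
        for key in row:
            if key not in fieldnames:
                fieldnames.append(key)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=fieldnames, quoting=csv.QUOTE_NONNUMERIC
        )
        writer.writeheader()
        writer.writerows(rows)


def _read_csv(path: Path) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        try:
            return [dict(row) for row in csv.DictReader(fh)]
        except csv.Error as exc:
            raise SurveyValidationError(f"malformed CSV {path}: {exc}")


def _export_csv(
    store: CentralStore, dest: Path, exam_layout: ExamLayout
) -> list[Path]:
    written = []
    for kind in ENTITY_TYPES:
        records = sorted(store.by_kind(kind), key=lambda r: r["record_uid"])
        if kind == "exam":
            long_rows = [
                row for rec in records for row in _exam_rows_per_tooth(rec)
            ]
            all_teeth = sorted(
                {
                    int(t)
                    for rec in records
                    for t in rec["payload"]["odontogram"]["teeth"]
                }
            )
            wide_rows = [_exam_row_wide(rec, all_teeth) for rec in records]
            for name, rows in (
                ("exams_per_tooth.csv", long_rows),
                ("exams_per_exam.csv", wide_rows),
            ):
                path = dest / name
                _write_csv(path, rows)
                written.append(path)
        else:
            path = dest / f"{kind}s.csv"
            _write_csv(path, [_flat_rows(rec, kind) for rec in records])
            written.append(path)
    return written


def _import_csv(dest: Path, exam_layout: ExamLayout) -> CentralStore:
    store = CentralStore()
    for kind in ENTITY_TYPES:
        if kind == "exam":
            if exam_layout == "per_tooth":
                rows = _read_csv(dest / "exams_per_tooth.csv")
                by_uid: dict[str, list[dict]] = {}
                for row in rows:
                    by_uid.setdefault(row["record_uid"], []).append(row)
                for uid, exam_rows in by_uid.items():
                    payload = _exam_payload_from_tooth_rows(exam_rows)
                    store.records[uid] = _rebuild_record(
                        "exam", exam_rows[0], payload
                    )
            else:
                for row in _read_csv(dest / "exams_per_exam.csv"):
                    payload = _exam_payload_from_wide_row(row)
                    store.records[row["record_uid"]] = _rebuild_record(
                        "exam", row, payload
                    )
        else:
            path = dest / f"{kind}s.csv"
            if not path.exists():
                continue
            for row in _read_csv(path):
                payload = _payload_from_flat(row, kind)
                store.records[row["record_uid"]] = _rebuild_record(
                    kind, row, payload
                )
    return store


# ---------------------------------------------------------------------------
# XML
# ---------------------------------------------------------------------------

def _export_xml(store: CentralStore, dest: Path) -> list[Path]:
    root = etree.Element("store", schema_version=store.records and next(
        iter(store.records.values())
    )["schema_version"] or "1.0")
    for record in sorted(store.records.values(), key=lambda r: r["record_uid"]):
        kind = record["kind"]
        el = etree.SubElement(root, kind, **{k: str(v) for k, v in _meta(record).items()})
        payload = record["payload"]
        if kind == "exam":
            for key in ("secret_code", "date", "examiner_id", "annotator_id"):
                el.set(key, payload[key])
            odo = etree.SubElement(
                el,
                "odontogram",
                teeth=" ".join(str(t) for t in payload["odontogram"]["teeth"]),
            )
            for tooth_str, rec in sorted(
                payload["odontogram"]["records"].items(),
                key=lambda kv: int(kv[0]),
            ):
                etree.SubElement(
                    odo,
                    "tooth",
                    code=str(rec["tooth"]),
                    crown=rec["crown"],
                    treatment=rec["treatment"],
                )
        elif kind == "response":
            for key in ("secret_code", "date"):
                el.set(key, payload[key])
            for q, a in sorted(
                payload["answers"].items(), key=lambda kv: int(kv[0])
            ):
                etree.SubElement(el, "answer", question=str(q), value=a)
        elif kind == "action":
            for key in ("id", "name", "campaign_id", "date_start", "date_end"):
                el.set(key, payload[key])
            for sid in payload["school_ids"]:
                etree.SubElement(el, "school", ref=sid)
        else:
            for key, value in payload.items():
                if value is not None:
                    el.set(key, str(value))
    path = dest / "store.xml"
    etree.ElementTree(root).write(
        str(path), encoding="utf-8", xml_declaration=True, pretty_print=True
    )
    return [path]


def _import_xml(dest: Path) -> CentralStore:
    path = dest / "store.xml"
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise SurveyValidationError(f"malformed XML {path}: {exc}")
    store = CentralStore()
    for el in root:
        kind = el.tag
        if kind not in ENTITY_TYPES:
            raise SurveyValidationError(
                f"{path} line {el.sourceline}: unknown record element {kind!r}"
            )
        meta = {k: el.get(k) for k in _META_COLS}
        attrs = {
            k: v for k, v in el.attrib.items() if k not in _META_COLS
        }
        payload: dict
        if kind == "exam":
            teeth_el = el.find("odontogram")
            payload = {
                **attrs,
                "odontogram": {
                    "teeth": [int(t) for t in teeth_el.get("teeth").split()],
                    "records": {
                        t.get("code"): {
                            "tooth": int(t.get("code")),
                            "crown": t.get("crown"),
                            "treatment": t.get("treatment"),
                        }
                        for t in teeth_el.findall("tooth")
                    },
                },
            }
        elif kind == "response":
            payload = {
                **attrs,
                "answers": {
                    a.get("question"): a.get("value")
                    for a in el.findall("answer")
                },
            }
        elif kind == "action":
            payload = {
                **attrs,
                "school_ids": [s.get("ref") for s in el.findall("school")],
            }
        else:
            payload = attrs
        store.records[meta["record_uid"]] = _rebuild_record(
            kind, meta, payload
        )
    return store


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _export_json(store: CentralStore, dest: Path) -> list[Path]:
    path = dest / "store.json"
    doc = {
        "records": sorted(
            store.records.values(), key=lambda r: r["record_uid"]
        )
    }
    path.write_text(canonical_json(doc) + "\n", encoding="utf-8")
    return [path]


def _import_json(dest: Path) -> CentralStore:
    path = dest / "store.json"
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SurveyValidationError(
            f"malformed JSON {path}: line {exc.lineno}: {exc.msg}"
        )
    store = CentralStore()
    for record in doc["records"]:
        store.records[record["record_uid"]] = record
    return store


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------

def export_store(
    store: CentralStore,
    dest: str | Path,
    fmt: Format = "csv",
    exam_layout: ExamLayout = "per_tooth",
) -> list[Path]:
    """Export a store to a directory in the requested format.

    CSV writes one file per entity kind, with exams in *both* layouts;
    XML and JSON write a single ``store.xml`` / ``store.json``.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        return _export_csv(store, dest, exam_layout)
    if fmt == "xml":
        return _export_xml(store, dest)
    if fmt == "json":
        return _export_json(store, dest)
    raise SurveyValidationError(f"unknown export format: {fmt!r}")


def import_store(
    src: str | Path,
    fmt: Format = "csv",
    exam_layout: ExamLayout = "per_tooth",
) -> CentralStore:
    """Import a store previously written by :func:`export_store`.

    The round trip is lossless at record level: re-importing an export
    reproduces the source records exactly.
    """
    src = Path(src)
    if fmt == "csv":
        return _import_csv(src, exam_layout)
    if fmt == "xml":
        return _import_xml(src)
    if fmt == "json":
        return _import_json(src)
    raise SurveyValidationError(f"unknown import format: {fmt!r}")
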