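"""Offline field capture and idempotent merge into the central store.

Field devices work without connectivity: records are appended to a
*local batch*, which is sealed (checksummed, frozen) before transport
and later merged into the central store.  The merge contract is the
heart of the sync protocol:

* records new to the store are inserted;
* a record with a known ``record_uid`` and identical content is a
  duplicate and skipped, so re-merging a batch is a no-op;
* a known ``record_uid`` with *different* content is a conflict,
  resolved last-write-wins by capture timestamp with an audit entry;
* records failing domain validation are quarantined, never inserted —
  the central store only ever holds valid records.

Batch files are JSON Lines with a header line, one canonical-JSON
record per line, and a footer carrying the checksum, so integrity is
verifiable bit-exactly across platforms.  At-rest encryption is a
pluggable byte codec (identity by default); key management is out of
scope, only the round-trip law ``decode(encode(x)) == x`` is enforced.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import random
import string
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Optional

from pydantic import BaseModel

from . import model as _model
from .model import SurveyValidationError, ValidationReport

SCHEMA_VERSION = _model.SCHEMA_VERSION

#: Record kind -> entity model; merge validation constructs the entity.
ENTITY_TYPES: dict[str, type[BaseModel]] = {
    "campaign": _model.Campaign,
    "action": _model.Action,
    "school": _model.School,
    "student": _model.Student,
    "exam": _model.Exam,
    "response": _model.QuestionnaireResponse,
}


def canonical_json(obj: Any) -> str:
    """Deterministic serialization: sorted keys, fixed separators, UTF-8
    preserved.  Checksums over this form are reproducible anywhere."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"),
                      ensure_ascii=False)


def make_record(
    kind: str,
    payload: BaseModel | dict,
    record_uid: Optional[str] = None,
    created_at: Optional[str] = None,
) -> dict:
    """Wrap an entity as a batch record with uid, kind and capture time."""
    if kind not in ENTITY_TYPES:
        raise SurveyValidationError(f"unknown record kind: {kind!r}")
    if isinstance(payload, BaseModel):
        payload = payload.model_dump(mode="json")
    return {
        "record_uid": record_uid or str(uuid.uuid4()),
        "kind": kind,
        "created_at": created_at
        or _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "schema_version": SCHEMA_VERSION,
        "payload": payload,
    }


def validate_record(record: dict) -> ValidationReport:
    """Domain validation of one batch record (structure + entity rules)."""
    report = ValidationReport()
    kind = record.get("kind")
    if kind not in ENTITY_TYPES:
        report.error("unknown_kind", f"unknown record kind: {kind!r}")
        return report
    for key in ("record_uid", "created_at", "payload"):
        if not record.get(key):
            report.error("missing_field", f"record missing {key!r}")
    if not report.ok:
        return report
    try:
        entity = ENTITY_TYPES[kind].model_validate(record["payload"])
    except Exception as exc:  # pydantic wraps SurveyValidationError
        report.error("invalid_payload", f"{kind} payload invalid: {exc}")
        return report
    if kind == "exam":
        exam_report = _model.validate_exam(entity)
        report.issues.extend(exam_report.issues)
    return report


# ---------------------------------------------------------------------------
# Local batches
# ---------------------------------------------------------------------------

def _records_checksum(records: Iterable[dict]) -> str:
    digest = hashlib.sha256()
    for rec in records:
        digest.update(canonical_json(rec).encode("utf-8"))
        digest.update(b"\n")
    return digest.hexdigest()


@dataclass
class LocalBatch:
    """A device-local record set; immutable once sealed."""

    batch_id: str
    device_label: str
    created_at: str
    records: list[dict] = field(default_factory=list)
    sealed: bool = False
    checksum: Optional[str] = None

    def append(self, record: dict) -> "LocalBatch":
        if self.sealed:
            raise SurveyValidationError(
                f"batch {self.batch_id} is sealed; cannot append"
            )
        self.records.append(record)
        return self

    def seal(self) -> "LocalBatch":
        """Compute the checksum and freeze content.  Idempotent."""
        if not self.sealed:
            self.checksum = _records_checksum(self.records)
            self.sealed = True
        return self

    def verify(self) -> bool:
        return (
            self.sealed
            and self.checksum == _records_checksum(self.records)
        )


def open_batch(
    device_label: str,
    batch_id: Optional[str] = None,
    created_at: Optional[str] = None,
) -> LocalBatch:
    """Start a new unsealed batch on a field device."""
    return LocalBatch(
        batch_id=batch_id or str(uuid.uuid4()),
        device_label=device_label,
        created_at=created_at
        or _dt.datetime.now(_dt.timezone.utc).isoformat(),
    )


def append_record(batch: LocalBatch, record: dict) -> LocalBatch:
    return batch.append(record)


def seal_batch(batch: LocalBatch) -> LocalBatch:
    return batch.seal()


def write_batch(batch: LocalBatch, path: str | Path) -> None:
    """Write a sealed batch as JSON Lines: header, records, checksum footer."""
    if not batch.sealed:
        raise SurveyValidationError("only sealed batches can be written")
    header = {
        "type": "header",
        "batch_id": batch.batch_id,
        "device_label": batch.device_label,
        "created_at": batch.created_at,
        "schema_version": SCHEMA_VERSION,
        "n_records": len(batch.records),
    }
    footer = {"type": "footer", "checksum": batch.checksum}
    lines = [canonical_json(header)]
    lines.extend(canonical_json(r) for r in batch.records)
    lines.append(canonical_json(footer))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_batch(path: str | Path) -> LocalBatch:
    """Load and integrity-check a batch file; tampering raises."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if len(lines) < 2:
        raise SurveyValidationError(f"batch file {path} is truncated")
    header = json.loads(lines[0])
    footer = json.loads(lines[-1])
    if header.get("type") != "header" or footer.get("type") != "footer":
        raise SurveyValidationError(f"batch file {path} is malformed")
    records = [json.loads(line) for line in lines[1:-1]]
    if len(records) != header.get("n_records"):
        raise SurveyValidationError(
            f"batch file {path}: header promises {header.get('n_records')} "
            f"records, found {len(records)}"
        )
    batch = LocalBatch(
        batch_id=header["batch_id"],
        device_label=header["device_label"],
        created_at=header["created_at"],
        records=records,
        sealed=True,
        checksum=footer.get("checksum"),
    )
    if not batch.verify():
        raise SurveyValidationError(
            f"batch file {path}: checksum mismatch (content tampered?)"
        )
    return batch


# ---------------------------------------------------------------------------
# Central store and merge
# ---------------------------------------------------------------------------

@dataclass
class MergeReport:
    """Outcome of merging one batch; every record lands in exactly one
    bucket (inserted / duplicate / conflict / quarantined)."""

    batch_id: str
    inserted: int = 0
    duplicates_skipped: int = 0
    conflicts: list[dict] = field(default_factory=list)
    quarantined: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return (
            self.inserted
            + self.duplicates_skipped
            + len(self.conflicts)
            + len(self.quarantined)
        )


class CentralStore:
    """Single-file central record store behind a small storage interface.

    Records live in memory keyed by ``record_uid``; :meth:`save` /
    :meth:`load` persist the whole store as one JSON document, run
    through the registered at-rest codec.
    """

    def __init__(self) -> None:
        self.records: dict[str, dict] = {}
        self.audit: list[dict] = []
        self._codec: "Codec" = IdentityCodec()

    # -- codec hook ---------------------------------------------------------
    def register_codec(self, codec: "Codec") -> None:
        self._codec = register_codec(codec)

    # -- queries ------------------------------------------------------------
    def by_kind(self, kind: str) -> list[dict]:
        return [r for r in self.records.values() if r["kind"] == kind]

    def entities(self, kind: str) -> list[BaseModel]:
        cls = ENTITY_TYPES[kind]
        return [cls.model_validate(r["payload"]) for r in self.by_kind(kind)]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records.values():
            out[r["kind"]] = out.get(r["kind"], 0) + 1
        return out

    def snapshot(self) -> str:
        """Canonical serialization of store content (audit excluded)."""
        return canonical_json(sorted(self.records.values(),
                                     key=lambda r: r["record_uid"]))

    # -- merge --------------------------------------------------------------
    def merge_batch(self, batch: LocalBatch) -> MergeReport:
        """Merge a sealed, checksum-valid batch.  See module docstring for
        the bucket semantics; idempotent and order-independent for
        batches with disjoint record uids."""
        if not batch.sealed:
            raise SurveyValidationError(
                f"batch {batch.batch_id} is not sealed"
            )
        if not batch.verify():
            raise SurveyValidationError(
                f"batch {batch.batch_id}: checksum mismatch"
            )
        report = MergeReport(batch_id=batch.batch_id)
        for record in batch.records:
            validation = validate_record(record)
            if not validation.ok:
                report.quarantined.append(
                    (
                        str(record.get("record_uid")),
                        [i.message for i in validation.errors],
                    )
                )
                continue
            uid = record["record_uid"]
            existing = self.records.get(uid)
            if existing is None:
                self.records[uid] = record
                report.inserted += 1
            elif canonical_json(existing) == canonical_json(record):
                report.duplicates_skipped += 1
            else:
                keep_incoming = record["created_at"] > existing["created_at"]
                resolution = "replaced_central" if keep_incoming else "kept_central"
                entry = {
                    "record_uid": uid,
                    "central_created_at": existing["created_at"],
                    "batch_created_at": record["created_at"],
                    "batch_id": batch.batch_id,
                    "resolution": resolution,
                }
                if keep_incoming:
                    self.records[uid] = record
                self.audit.append(entry)
                report.conflicts.append(entry)
        return report

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "records": sorted(
                self.records.values(), key=lambda r: r["record_uid"]
            ),
            "audit": self.audit,
        }
        payload = self._codec.encode(canonical_json(doc).encode("utf-8"))
        Path(path).write_bytes(payload)

    @classmethod
    def load(cls, path: str | Path, codec: "Codec | None" = None) -> "CentralStore":
        store = cls()
        if codec is not None:
            store.register_codec(codec)
        raw = store._codec.decode(Path(path).read_bytes())
        doc = json.loads(raw.decode("utf-8"))
        store.records = {r["record_uid"]: r for r in doc["records"]}
        store.audit = doc.get("audit", [])
        return store


# ---------------------------------------------------------------------------
# At-rest codec hook
# ---------------------------------------------------------------------------

class Codec:
    """Byte-level at-rest transform; must satisfy decode(encode(x)) == x."""

    def encode(self, payload: bytes) -> bytes:  # pragma: no cover - interface
        raise NotImplementedError

    def decode(self, payload: bytes) -> bytes:  # pragma: no cover - interface
        raise NotImplementedError


class IdentityCodec(Codec):
    """Pass-through default: stored bytes equal logical bytes."""

    def encode(self, payload: bytes) -> bytes:
        return payload

    def decode(self, payload: bytes) -> bytes:
        return payload


_PROBE_PAYLOAD = canonical_json(
    {"probe": "round-trip", "bytes": list(range(32)), "text": "áéíóú ãõ ç"}
).encode("utf-8")


def register_codec(codec: Codec) -> Codec:
    """Admit a codec after verifying the round-trip law on a probe payload."""
    try:
        restored = codec.decode(codec.encode(_PROBE_PAYLOAD))
    except Exception as exc:
        raise SurveyValidationError(f"codec failed round-trip probe: {exc}")
    if restored != _PROBE_PAYLOAD:
        raise SurveyValidationError(
            "codec rejected: decode(encode(x)) != x on probe payload"
        )
    return codec


# ---------------------------------------------------------------------------
# Secret codes
# ---------------------------------------------------------------------------

_CODE_ALPHABET = string.ascii_uppercase + string.digits


class SecretCodeGenerator:
    """Issues opaque, campaign-unique student codes.

    The code carries no personal information by construction (drawn from
    a fixed alphabet, independent of any student field).  Seedable so
    tests and simulations are reproducible.
    """

    def __init__(self, seed: Optional[int] = None, length: int = 8) -> None:
        if length < 4:
            raise SurveyValidationError("secret codes must be >= 4 characters")
        self._rng = random.Random(seed)
        self._length = length
        self._issued: set[str] = set()

    def issue(self) -> str:
        # 36^8 ~ 2.8e12 codes: exhaustion is practically unreachable, but
        # guard against a pathological configuration anyway.
        space = len(_CODE_ALPHABET) ** self._length
        if len(self._issued) >= space:
            raise SurveyValidationError("secret code space exhausted")
        while True:
            code = "".join(
                self._rng.choice(_CODE_ALPHABET) for _ in range(self._length)
            )
            if code not in self._issued:
                self._issued.add(code)
                return code


def issue_secret_code(generator: SecretCodeGenerator) -> str:
    return generator.issue()
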