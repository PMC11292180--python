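"""Sample lifecycle management.

Submitted manifests become per-sample broker records that move through
PENDING -> ACCEPTED|REJECTED and ACCEPTED -> SUBMITTED.  Submission is
gated on a passing validation report and the submitter role; review
(accept/reject, singly or in bundles) requires the supervisor role.
Registration mints one BioSample accession per sample *and* per
specimen-level sample, plus a ToLID public name per specimen.  Every
metadata change is recorded in an append-only audit trail (what changed,
old and new value, when, by whom), and supervisor notification is
modelled as an append-only event log.

Persistence is an embedded sqlite store; the default ``:memory:`` path
gives a throwaway store for tests and desk use.

The accession and ToLID minters here are deliberately mock schemes
(``SAMEA``/``ERS`` + counter, and ``<prefix><Genus3><species4><n>``):
they are non-authoritative stand-ins behind the same interface a real
registry client would implement.
"""
from __future__ import annotations

import json
import re
import sqlite3
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path

from .errors import (AccessionError, InvalidTransition, NotFound,
                     SubmissionRefused, UpdateRejected)
from .graph import make_sample_key
from .manifest import Manifest, ManifestRecord
from .validate import ValidationReport, validate_field_phase

STATES = ("PENDING", "REJECTED", "ACCEPTED", "SUBMITTED")
ALLOWED_TRANSITIONS = {
    ("PENDING", "ACCEPTED"), ("PENDING", "REJECTED"),
    ("ACCEPTED", "SUBMITTED"),
}

ROLES = ("SAMPLE_SUBMITTER", "SAMPLE_SUPERVISOR")


@dataclass(frozen=True)
class UserRole:
    name: str
    role: str  # SAMPLE_SUBMITTER | SAMPLE_SUPERVISOR


@dataclass
class BrokerRecord:
    sample_key: str
    specimen_id: str
    state: str
    schema_version: str
    profile: str = "default"
    biosample_accession: str | None = None
    ena_accession: str | None = None
    tolid: str | None = None
    metadata: dict = dc_field(default_factory=dict)


@dataclass(frozen=True)
class AuditEntry:
    timestamp: str
    actor: str
    sample_key: str
    field: str
    old_value: str
    new_value: str


@dataclass(frozen=True)
class ImageAssociation:
    specimen_id: str
    index: int
    path: str


class AccessionMinter:
    """Counter-backed mock accession minter (e.g. SAMEA00000001)."""

    def __init__(self, prefix: str = "SAMEA", width: int = 8, start: int = 1):
        self.prefix = prefix
        self.width = width
        self._next = start
        self._issued: set[str] = set()

    def mint(self) -> str:
        accession = f"{self.prefix}{self._next:0{self.width}d}"
        self._next += 1
        if accession in self._issued:
            raise AccessionError(f"duplicate accession {accession}")
        self._issued.add(accession)
        return accession


@dataclass
class ToLIDMinter:
    """Mock ToLID scheme: ``<prefix><Genus3><species4><n>``.

    ``n`` counts specimens per species in order of first assignment, so
    the same (species, specimen) pair always yields the same name.
    """

    prefix: str = "xx"
    memo: dict = dc_field(default_factory=dict)      # (species, specimen) -> tolid
    counters: dict = dc_field(default_factory=dict)  # stem -> last suffix


def tolid_stem(species_name: str, prefix: str = "xx") -> str:
    parts = re.split(r"\s+", species_name.strip())
    genus = parts[0] if parts else ""
    epithet = parts[1] if len(parts) > 1 else ""
    return f"{prefix}{genus[:3].capitalize()}{epithet[:4].lower()}"


def assign_tolid(species_name: str, specimen_id: str,
                 minter_state: ToLIDMinter) -> str:
    """Deterministically assign (or recall) the ToLID for a specimen."""
    key = (species_name, specimen_id)
    if key in minter_state.memo:
        return minter_state.memo[key]
    stem = tolid_stem(species_name, minter_state.prefix)
    n = minter_state.counters.get(stem, 0) + 1
    minter_state.counters[stem] = n
    tolid = f"{stem}{n}"
    minter_state.memo[key] = tolid
    return tolid


_IMAGE_EXTENSIONS = {"png", "jpg"}
_INDEXED = re.compile(r"^(?P<stem>.+)_(?P<index>\d+)$")


def parse_image_name(filename: str,
                     known_specimen_ids=None) -> ImageAssociation | None:
    """Associate an image file name with a specimen.

    ``<SPECIMEN_ID>_<n>.png|jpg`` maps to (SPECIMEN_ID, n) and a bare
    ``<SPECIMEN_ID>.png|jpg`` to index 1.  Because specimen ids may
    themselves contain underscores, known ids are tried first (longest
    match); only then does the trailing ``_<n>`` split apply.  Returns
    ``None`` for anything that does not match — the caller reports
    unmatched files as a warning, never a failure.
    """
    path = Path(filename)
    ext = path.suffix.lstrip(".").lower()
    if ext not in _IMAGE_EXTENSIONS:
        return None
    stem = path.stem
    if known_specimen_ids:
        for spid in sorted(known_specimen_ids, key=len, reverse=True):
            if stem == spid:
                return ImageAssociation(spid, 1, str(filename))
            if stem.startswith(spid + "_"):
                suffix = stem[len(spid) + 1:]
                if suffix.isdigit():
                    return ImageAssociation(spid, int(suffix), str(filename))
    match = _INDEXED.match(stem)
    if match:
        return ImageAssociation(match["stem"], int(match["index"]),
                                str(filename))
    return ImageAssociation(stem, 1, str(filename)) if stem else None


def _utcnow() -> str:
    return datetime.now(timezone.utc).isoformat()


_SCHEMA_SQL = """
CREATE TABLE IF NOT EXISTS samples (
    sample_key TEXT PRIMARY KEY,
    specimen_id TEXT NOT NULL,
    state TEXT NOT NULL,
    schema_version TEXT NOT NULL,
    profile TEXT NOT NULL,
    biosample_accession TEXT,
    ena_accession TEXT,
    metadata TEXT NOT NULL,
    submitted_metadata TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS specimens (
    specimen_id TEXT PRIMARY KEY,
    taxon_id TEXT,
    biosample_accession TEXT,
    tolid TEXT
);
CREATE TABLE IF NOT EXISTS audit (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    ts TEXT NOT NULL,
    actor TEXT NOT NULL,
    sample_key TEXT NOT NULL,
    field TEXT NOT NULL,
    old_value TEXT NOT NULL,
    new_value TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS events (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    ts TEXT NOT NULL,
    kind TEXT NOT NULL,
    payload TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS images (
    specimen_id TEXT NOT NULL,
    idx INTEGER NOT NULL,
    path TEXT NOT NULL,
    UNIQUE (specimen_id, idx)
);
"""


class Broker:
    """The persistent store plus every lifecycle operation over it."""

    def __init__(self, store_path: str | Path = ":memory:",
                 schema_loader=None):
        self.db = sqlite3.connect(str(store_path))
        self.db.executescript(_SCHEMA_SQL)
        if schema_loader is None:
            from .schemas import load_schema
            schema_loader = lambda v: load_schema("dtol-core", v)  # noqa: E731
        self._schema_loader = schema_loader
        self.biosample_minter = AccessionMinter("SAMEA", 8)
        self.ena_minter = AccessionMinter("ERS", 7)
        self.tolid_minter = ToLIDMinter()

    def close(self):
        self.db.close()

    # -- internal helpers -------------------------------------------------

    def _audit(self, actor: str, sample_key: str, field: str,
               old: str, new: str) -> None:
        self.db.execute(
            "INSERT INTO audit (ts, actor, sample_key, field, old_value,"
            " new_value) VALUES (?,?,?,?,?,?)",
            (_utcnow(), actor, sample_key, field, old, new),
        )

    def _event(self, kind: str, payload: dict) -> None:
        self.db.execute(
            "INSERT INTO events (ts, kind, payload) VALUES (?,?,?)",
            (_utcnow(), kind, json.dumps(payload, sort_keys=True)),
        )

    def _row_to_record(self, row) -> BrokerRecord:
        (sample_key, specimen_id, state, schema_version, profile,
         biosample, ena, metadata) = row
        tolid = self.db.execute(
            "SELECT tolid FROM specimens WHERE specimen_id = ?",
            (specimen_id,)).fetchone()
        return BrokerRecord(
            sample_key=sample_key, specimen_id=specimen_id, state=state,
            schema_version=schema_version, profile=profile,
            biosample_accession=biosample, ena_accession=ena,
            tolid=tolid[0] if tolid else None,
            metadata=json.loads(metadata),
        )

    _RECORD_COLS = ("sample_key, specimen_id, state, schema_version, "
                    "profile, biosample_accession, ena_accession, metadata")

    # -- registry interface used by validate_cross_phase ------------------

    def registered_taxon(self, specimen_id: str) -> str | None:
        row = self.db.execute(
            "SELECT taxon_id FROM specimens WHERE specimen_id = ?",
            (specimen_id,)).fetchone()
        return row[0] if row and row[0] else None

    # -- lifecycle operations ---------------------------------------------

    def submit_manifest(self, manifest: Manifest, report: ValidationReport,
                        submitter: UserRole,
                        profile: str = "default") -> list[BrokerRecord]:
        """Create one PENDING record per manifest row and notify the
        supervisors (as an event)."""
        if submitter.role != "SAMPLE_SUBMITTER":
            raise PermissionError(
                f"{submitter.name} ({submitter.role}) cannot submit manifests")
        if not report.passed:
            raise SubmissionRefused(
                f"validation failed with {len(report.errors())} error(s)")
        created: list[BrokerRecord] = []
        with self.db:
            for record in manifest.records:
                sample_key = make_sample_key(record.get("RACK_OR_PLATE_ID"),
                                             record.get("TUBE_OR_WELL_ID"))
                metadata_json = json.dumps(record.values, sort_keys=True)
                self.db.execute(
                    "INSERT INTO samples (sample_key, specimen_id, state,"
                    " schema_version, profile, metadata, submitted_metadata)"
                    " VALUES (?,?,?,?,?,?,?)",
                    (sample_key, record.get("SPECIMEN_ID"), "PENDING",
                     manifest.schema_version, profile, metadata_json,
                     metadata_json),
                )
                self.db.execute(
                    "INSERT OR IGNORE INTO specimens (specimen_id, taxon_id)"
                    " VALUES (?,?)",
                    (record.get("SPECIMEN_ID"), record.get("TAXON_ID")),
                )
                self._audit(submitter.name, sample_key, "_state", "",
                            "PENDING")
                created.append(self.query_sample(sample_key))
            if created:
                self._event("MANIFEST_AWAITING_REVIEW", {
                    "submitter": submitter.name,
                    "profile": profile,
                    "n_samples": len(created),
                    "schema_version": manifest.schema_version,
                })
        return created

    def review(self, sample_keys: list[str], decision: str,
               supervisor: UserRole) -> list[BrokerRecord]:
        """Accept or reject pending samples, singly or in bundles."""
        if supervisor.role != "SAMPLE_SUPERVISOR":
            raise PermissionError(
                f"{supervisor.name} ({supervisor.role}) cannot review samples")
        if decision not in ("ACCEPT", "REJECT"):
            raise ValueError(f"unknown decision {decision!r}")
        new_state = "ACCEPTED" if decision == "ACCEPT" else "REJECTED"
        updated = []
        with self.db:
            for key in sample_keys:
                rec = self.query_sample(key)
                if (rec.state, new_state) not in ALLOWED_TRANSITIONS:
                    raise InvalidTransition(
                        f"sample {key} is {rec.state}, not PENDING")
                self.db.execute(
                    "UPDATE samples SET state = ? WHERE sample_key = ?",
                    (new_state, key))
                self._audit(supervisor.name, key, "_state", rec.state,
                            new_state)
                updated.append(self.query_sample(key))
        return updated

    def register_accepted(self, accession_minter=None, ena_minter=None,
                          tolid_minter=None,
                          actor: str = "registration-queue"
                          ) -> list[BrokerRecord]:
        """Drain the registration queue: mint accessions and ToLIDs.

        Every ACCEPTED sample and its specimen-level parent gets a
        unique BioSample accession; each specimen additionally gets a
        ToLID.  Idempotent: a second call finds nothing ACCEPTED and
        mints nothing.
        """
        biosample = accession_minter or self.biosample_minter
        ena = ena_minter or self.ena_minter
        tolids = tolid_minter or self.tolid_minter
        registered = []
        with self.db:
            rows = self.db.execute(
                f"SELECT {self._RECORD_COLS} FROM samples WHERE state ="
                " 'ACCEPTED' ORDER BY sample_key").fetchall()
            for row in rows:
                rec = self._row_to_record(row)
                sp_row = self.db.execute(
                    "SELECT biosample_accession, tolid FROM specimens"
                    " WHERE specimen_id = ?", (rec.specimen_id,)).fetchone()
                sp_accession, sp_tolid = sp_row if sp_row else (None, None)
                if sp_accession is None:
                    sp_accession = biosample.mint()
                if sp_tolid is None:
                    species = rec.metadata.get("SCIENTIFIC_NAME", "")
                    sp_tolid = assign_tolid(species, rec.specimen_id, tolids)
                self.db.execute(
                    "INSERT INTO specimens (specimen_id, biosample_accession,"
                    " tolid) VALUES (?,?,?) ON CONFLICT(specimen_id) DO"
                    " UPDATE SET biosample_accession = excluded"
                    ".biosample_accession, tolid = excluded.tolid",
                    (rec.specimen_id, sp_accession, sp_tolid))
                self.db.execute(
                    "UPDATE samples SET state = 'SUBMITTED',"
                    " biosample_accession = ?, ena_accession = ?"
                    " WHERE sample_key = ?",
                    (biosample.mint(), ena.mint(), rec.sample_key))
                self._audit(actor, rec.sample_key, "_state", "ACCEPTED",
                            "SUBMITTED")
                registered.append(self.query_sample(rec.sample_key))
        return registered

    def update_sample(self, sample_key: str, changes: dict,
                      actor: UserRole, taxonomy=None) -> BrokerRecord:
        """Apply a metadata update atomically, after re-validation.

        The changed record is validated against the schema version it
        was originally submitted under; any ERROR rejects the whole
        change set.  One audit entry is written per actually-changed
        field.
        """
        rec = self.query_sample(sample_key)
        merged = {**rec.metadata, **{k: str(v) for k, v in changes.items()}}
        schema = self._schema_loader(rec.schema_version)
        probe = Manifest(
            schema_version=rec.schema_version,
            records=[ManifestRecord(row_index=1, values=merged)],
        )
        issues = validate_field_phase(probe, schema)
        if taxonomy is not None and (
                "SCIENTIFIC_NAME" in changes or "TAXON_ID" in changes):
            from .taxonomy import reconcile_record
            _, tax_issues = reconcile_record(probe.records[0], taxonomy)
            issues.extend(tax_issues)
        errors = [i for i in issues if i.severity == "ERROR"]
        if errors:
            raise UpdateRejected(errors)
        with self.db:
            for field_name, new_value in sorted(changes.items()):
                old_value = rec.metadata.get(field_name, "")
                if str(new_value) == old_value:
                    continue
                self._audit(actor.name, sample_key, field_name, old_value,
                            str(new_value))
            self.db.execute(
                "UPDATE samples SET metadata = ? WHERE sample_key = ?",
                (json.dumps(merged, sort_keys=True), sample_key))
        return self.query_sample(sample_key)

    def query_sample(self, key: str) -> BrokerRecord:
        """Look a sample up by sample key or by any minted accession."""
        row = self.db.execute(
            f"SELECT {self._RECORD_COLS} FROM samples WHERE sample_key = ?"
            " OR biosample_accession = ? OR ena_accession = ?",
            (key, key, key)).fetchone()
        if row is None:
            sp = self.db.execute(
                "SELECT specimen_id FROM specimens WHERE biosample_accession"
                " = ? OR tolid = ?", (key, key)).fetchone()
            if sp:
                row = self.db.execute(
                    f"SELECT {self._RECORD_COLS} FROM samples WHERE"
                    " specimen_id = ? ORDER BY sample_key", (sp[0],)
                ).fetchone()
        if row is None:
            raise NotFound(f"no sample matches {key!r}")
        return self._row_to_record(row)

    def records(self, state: str | None = None) -> list[BrokerRecord]:
        sql = f"SELECT {self._RECORD_COLS} FROM samples"
        args: tuple = ()
        if state is not None:
            sql += " WHERE state = ?"
            args = (state,)
        sql += " ORDER BY sample_key"
        return [self._row_to_record(r) for r in self.db.execute(sql, args)]

    # -- audit / events / images ------------------------------------------

    def audit_trail(self, sample_key: str | None = None) -> list[AuditEntry]:
        sql = ("SELECT ts, actor, sample_key, field, old_value, new_value"
               " FROM audit")
        args: tuple = ()
        if sample_key is not None:
            sql += " WHERE sample_key = ?"
            args = (sample_key,)
        sql += " ORDER BY id"
        return [AuditEntry(*row) for row in self.db.execute(sql, args)]

    def submitted_metadata(self, sample_key: str) -> dict:
        row = self.db.execute(
            "SELECT submitted_metadata FROM samples WHERE sample_key = ?",
            (sample_key,)).fetchone()
        if row is None:
            raise NotFound(f"no sample matches {sample_key!r}")
        return json.loads(row[0])

    def events(self) -> list[dict]:
        return [
            {"ts": ts, "kind": kind, **json.loads(payload)}
            for ts, kind, payload in self.db.execute(
                "SELECT ts, kind, payload FROM events ORDER BY id")
        ]

    def known_specimen_ids(self) -> list[str]:
        return [r[0] for r in
                self.db.execute("SELECT specimen_id FROM specimens")]

    def attach_images(self, filenames) -> tuple[list[ImageAssociation],
                                                list[str]]:
        """Associate image files with known specimens.

        Returns (stored associations, unmatched file names); unmatched
        files are reported, never fatal.
        """
        known = set(self.known_specimen_ids())
        stored: list[ImageAssociation] = []
        unmatched: list[str] = []
        with self.db:
            for filename in filenames:
                assoc = parse_image_name(filename, known)
                if assoc is None or assoc.specimen_id not in known:
                    unmatched.append(str(filename))
                    continue
                self.db.execute(
                    "INSERT OR REPLACE INTO images (specimen_id, idx, path)"
                    " VALUES (?,?,?)",
                    (assoc.specimen_id, assoc.index, assoc.path))
                stored.append(assoc)
        return stored, unmatched

    def images(self, specimen_id: str) -> list[ImageAssociation]:
        return [ImageAssociation(*row) for row in self.db.execute(
            "SELECT specimen_id, idx, path FROM images WHERE specimen_id = ?"
            " ORDER BY idx", (specimen_id,))]
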