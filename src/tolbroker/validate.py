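"""Three-phase manifest validation.

Phase 1 (TAXONOMY) reconciles every row against the taxonomy snapshot;
any taxonomy ERROR aborts the remaining phases, mirroring a brokering
workflow in which submission stops when taxonomic integrity fails.
Phase 2 (FIELD) checks each cell against its field specification:
mandatory presence, controlled vocabulary, date format, coordinate
ranges, and the tube/well barcode format (a warning, not an error).
Phase 3 (CROSS) applies semantic rules across rows and against the
broker registry: a specimen must keep one taxon, a whole organism can
occupy only one tube, and the rack/plate + tube/well pair that
identifies a sample must be unique.

Issue codes form a stable catalogue so downstream tooling can key on
them:

ERROR:   TAXON_NOT_FOUND, TAXON_NOT_SUBMITTABLE, TAXON_NOT_SPECIES_RANK,
         TAXON_ID_NAME_MISMATCH, MISSING_MANDATORY, VOCAB_VIOLATION,
         BAD_DATE, BAD_COORDINATE, SPECIMEN_TAXON_CONFLICT,
         DUPLICATE_WHOLE_ORGANISM, DUPLICATE_SAMPLE_ID
WARNING: SYNONYM_CONVERTED, PARTIAL_DATE, NONSTANDARD_TUBE_ID
"""
from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field as dc_field

from .manifest import Manifest, ManifestRecord, SENTINELS
from .schemas import ManifestSchema
from .taxonomy import TaxonomyTable, reconcile_record

RULE_CATALOGUE = frozenset({
    "SYNONYM_CONVERTED", "TAXON_NOT_FOUND", "TAXON_NOT_SUBMITTABLE",
    "TAXON_NOT_SPECIES_RANK", "TAXON_ID_NAME_MISMATCH", "MISSING_MANDATORY",
    "VOCAB_VIOLATION", "BAD_DATE", "PARTIAL_DATE", "BAD_COORDINATE",
    "NONSTANDARD_TUBE_ID", "SPECIMEN_TAXON_CONFLICT",
    "DUPLICATE_WHOLE_ORGANISM", "DUPLICATE_SAMPLE_ID",
})

#: Codes emitted with ERROR severity by the taxonomy phase; any of them
#: aborts the field and cross phases.
TAXONOMY_ERROR_CODES = frozenset({
    "TAXON_NOT_FOUND", "TAXON_NOT_SUBMITTABLE",
    "TAXON_NOT_SPECIES_RANK", "TAXON_ID_NAME_MISMATCH",
})

#: Default tube/well barcode format (configurable per deployment).
DEFAULT_BARCODE_PATTERN = r"^[A-Za-z0-9]+$"

_FULL_DATE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_PARTIAL_DATE = re.compile(r"^\d{4}(-\d{2})?$")

_COORDINATE_RANGES = {
    "DECIMAL_LATITUDE": (-90.0, 90.0),
    "DECIMAL_LONGITUDE": (-180.0, 180.0),
}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str          # ERROR | WARNING
    code: str              # stable token from RULE_CATALOGUE
    row_index: int | None  # None for manifest-level issues
    field: str | None
    message: str

    def __post_init__(self):
        assert self.code in RULE_CATALOGUE, self.code

    def key(self) -> tuple:
        return (self.row_index or 0, self.field or "", self.code)

    def to_dict(self) -> dict:
        return {
            "severity": self.severity, "code": self.code,
            "row_index": self.row_index, "field": self.field,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    phase_reached: str  # TAXONOMY | FIELD | CROSS
    issues: list[ValidationIssue] = dc_field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(i.severity == "ERROR" for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "ERROR"]

    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "WARNING"]

    def codes(self) -> set[str]:
        return {i.code for i in self.issues}

    def to_dict(self) -> dict:
        return {
            "phase_reached": self.phase_reached,
            "passed": self.passed,
            "issues": [i.to_dict() for i in self.issues],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _sorted(issues) -> list[ValidationIssue]:
    return sorted(issues, key=ValidationIssue.key)


def validate_taxonomy_phase(manifest: Manifest, table: TaxonomyTable):
    """Reconcile every row; returns (manifest with populated taxonomic
    fields, issues)."""
    issues: list[ValidationIssue] = []
    updated: list[ManifestRecord] = []
    for record in manifest.records:
        if "SCIENTIFIC_NAME" in record.values or "TAXON_ID" in record.values:
            rec, rec_issues = reconcile_record(record, table)
            issues.extend(rec_issues)
            updated.append(rec)
        else:
            updated.append(record)
    return (
        Manifest(schema_version=manifest.schema_version, records=updated,
                 provenance=manifest.provenance),
        issues,
    )


def _check_date(value: str):
    """Classify a date cell; full ISO dates must be real calendar dates."""
    if _FULL_DATE.match(value):
        try:
            _dt.date.fromisoformat(value)
            return None
        except ValueError:
            return "BAD_DATE"
    if _PARTIAL_DATE.match(value):
        return "PARTIAL_DATE"
    return "BAD_DATE"


def validate_field_phase(manifest: Manifest, schema: ManifestSchema,
                         barcode_pattern: str = DEFAULT_BARCODE_PATTERN):
    """Per-cell compliance with the field catalogue."""
    issues: list[ValidationIssue] = []
    barcode = re.compile(barcode_pattern)

    def add(severity, code, record, fname, message):
        issues.append(ValidationIssue(severity, code, record.row_index,
                                      fname, message))

    for record in manifest.records:
        for spec in schema.fields:
            value = record.get(spec.name)
            is_sentinel = value in SENTINELS
            vocab_fold = {v.casefold() for v in spec.vocabulary}
            # A sentinel satisfies a field only where the SOP admits it:
            # vocabularies that list it, and verbatim-captured dates.
            sentinel_allowed = is_sentinel and (
                value.casefold() in vocab_fold or spec.value_kind == "DATE")
            if not value or (is_sentinel and not sentinel_allowed):
                if spec.requirement == "MANDATORY":
                    add("ERROR", "MISSING_MANDATORY", record, spec.name,
                        f"mandatory field {spec.name} is "
                        + (f"the sentinel {value!r}" if value else "empty"))
                continue
            if is_sentinel:
                continue
            if spec.value_kind == "CONTROLLED":
                if value.casefold() not in vocab_fold:
                    add("ERROR", "VOCAB_VIOLATION", record, spec.name,
                        f"{value!r} is not an allowed term for {spec.name}")
            elif spec.value_kind == "DATE":
                verdict = _check_date(value)
                if verdict == "BAD_DATE":
                    add("ERROR", "BAD_DATE", record, spec.name,
                        f"{value!r} is not an ISO-8601 YYYY-MM-DD date")
                elif verdict == "PARTIAL_DATE":
                    add("WARNING", "PARTIAL_DATE", record, spec.name,
                        f"{value!r} is a partial date")
            elif spec.name in _COORDINATE_RANGES:
                lo, hi = _COORDINATE_RANGES[spec.name]
                try:
                    coord = float(value)
                except ValueError:
                    add("ERROR", "BAD_COORDINATE", record, spec.name,
                        f"{value!r} is not a decimal coordinate")
                else:
                    if not lo <= coord <= hi:
                        add("ERROR", "BAD_COORDINATE", record, spec.name,
                            f"{value!r} outside [{lo}, {hi}]")
            if spec.name == "TUBE_OR_WELL_ID" and value \
                    and not barcode.match(value):
                add("WARNING", "NONSTANDARD_TUBE_ID", record, spec.name,
                    f"tube/well id {value!r} does not match the standard "
                    "barcode format")
    return issues


def validate_cross_phase(manifest: Manifest, registry=None):
    """Cross-row and cross-manifest semantic rules.

    ``registry``, when given, is anything with a
    ``registered_taxon(specimen_id) -> taxon_id | None`` method (the
    broker store provides one) used to detect a specimen resubmitted
    under a different taxon.
    """
    issues: list[ValidationIssue] = []
    by_specimen: dict[str, list[ManifestRecord]] = {}
    by_sample_key: dict[tuple[str, str], list[ManifestRecord]] = {}
    for record in manifest.records:
        spid = record.get("SPECIMEN_ID")
        if spid:
            by_specimen.setdefault(spid, []).append(record)
        rack, tube = record.get("RACK_OR_PLATE_ID"), record.get("TUBE_OR_WELL_ID")
        if rack or tube:
            by_sample_key.setdefault((rack, tube), []).append(record)

    for spid, group in by_specimen.items():
        taxa = {r.get("TAXON_ID") for r in group if r.get("TAXON_ID")}
        if len(taxa) > 1:
            for record in group:
                issues.append(ValidationIssue(
                    "ERROR", "SPECIMEN_TAXON_CONFLICT", record.row_index,
                    "SPECIMEN_ID",
                    f"specimen {spid} is associated with taxa "
                    f"{sorted(taxa)}"))
        if len(group) > 1 and any(
                r.get("ORGANISM_PART") == "WHOLE_ORGANISM" for r in group):
            for record in group:
                issues.append(ValidationIssue(
                    "ERROR", "DUPLICATE_WHOLE_ORGANISM", record.row_index,
                    "SPECIMEN_ID",
                    f"specimen {spid} appears in {len(group)} rows but one "
                    "of them is a whole organism"))
        if registry is not None:
            prior = registry.registered_taxon(spid)
            if prior is not None and taxa and {str(prior)} != taxa:
                for record in group:
                    issues.append(ValidationIssue(
                        "ERROR", "SPECIMEN_TAXON_CONFLICT", record.row_index,
                        "SPECIMEN_ID",
                        f"specimen {spid} was previously registered with "
                        f"taxon {prior}"))

    for (rack, tube), group in by_sample_key.items():
        if len(group) > 1:
            for record in group:
                issues.append(ValidationIssue(
                    "ERROR", "DUPLICATE_SAMPLE_ID", record.row_index,
                    "TUBE_OR_WELL_ID",
                    f"sample id {rack}/{tube} occurs in "
                    f"{len(group)} rows"))
    return issues


def run_validation(manifest: Manifest, schema: ManifestSchema,
                   table: TaxonomyTable, registry=None,
                   barcode_pattern: str = DEFAULT_BARCODE_PATTERN):
    """Run all three phases in order and assemble the gating report.

    Returns ``(reconciled_manifest, ValidationReport)``.  A taxonomy
    ERROR stops the pipeline (``phase_reached == "TAXONOMY"``);
    otherwise the field and cross phases both run so the submitter sees
    every remaining problem at once.  Warnings never block.
    """
    reconciled, issues = validate_taxonomy_phase(manifest, table)
    if any(i.severity == "ERROR" for i in issues):
        return reconciled, ValidationReport("TAXONOMY", _sorted(issues))
    issues.extend(validate_field_phase(reconciled, schema, barcode_pattern))
    issues.extend(validate_cross_phase(reconciled, registry))
    return reconciled, ValidationReport("CROSS", _sorted(issues))
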