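"""Local taxonomy resolution.

Scientific names must be supplied at species rank, match the main name
of a submittable taxon, or be convertible to it: synonyms resolve to
the main name with a warning so the curated name is what gets stored.
The taxonomy is a local pinned snapshot in a simple TSV form (columns
``taxon_id, name, name_class, rank, submittable``); a live query client
can implement the same lookup surface later.  Pinning keeps validation
reproducible — upstream taxonomies change frequently enough to flip a
previously valid manifest.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .errors import TaxonomyIntegrityError
from .manifest import ManifestRecord

NAME_CLASSES = ("MAIN", "SYNONYM")
RANKS = ("SPECIES", "GENUS", "FAMILY", "OTHER")

# Resolution statuses, worst first (precedence order).
STATUS_ORDER = (
    "NOT_FOUND",
    "ID_NAME_MISMATCH",
    "NOT_SPECIES_RANK",
    "NOT_SUBMITTABLE",
    "SYNONYM_CONVERTED",
    "MAIN_MATCH",
)


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: int
    name: str
    name_class: str  # MAIN | SYNONYM
    rank: str        # SPECIES | GENUS | FAMILY | OTHER
    submittable: bool


@dataclass
class TaxonResolution:
    status: str
    taxon_id: int | None = None
    main_name: str | None = None
    warnings: list[str] = dc_field(default_factory=list)


class TaxonomyTable:
    """In-memory lookup over taxon records, by id and by folded name."""

    def __init__(self, records: list[TaxonRecord]):
        self.records = records
        self._main_by_id: dict[int, TaxonRecord] = {}
        self._by_name: dict[str, list[TaxonRecord]] = {}
        seen_pairs: set[tuple[int, str, str]] = set()
        for rec in records:
            key = (rec.taxon_id, rec.name.casefold(), rec.name_class)
            if key in seen_pairs:
                raise TaxonomyIntegrityError(
                    f"duplicate ({rec.name!r}, {rec.name_class}) for taxon "
                    f"{rec.taxon_id}"
                )
            seen_pairs.add(key)
            if rec.name_class == "MAIN":
                if rec.taxon_id in self._main_by_id:
                    raise TaxonomyIntegrityError(
                        f"two MAIN names for taxon {rec.taxon_id}"
                    )
                self._main_by_id[rec.taxon_id] = rec
            self._by_name.setdefault(rec.name.casefold(), []).append(rec)
        for rec in records:
            if rec.taxon_id not in self._main_by_id:
                raise TaxonomyIntegrityError(
                    f"taxon {rec.taxon_id} has no MAIN name"
                )

    def __len__(self) -> int:
        return len(self._main_by_id)

    def main(self, taxon_id: int) -> TaxonRecord | None:
        return self._main_by_id.get(taxon_id)

    def find_name(self, name: str) -> TaxonRecord | None:
        """Best record for a name: a MAIN match beats a SYNONYM match."""
        hits = self._by_name.get(name.strip().casefold(), [])
        for rec in hits:
            if rec.name_class == "MAIN":
                return rec
        return hits[0] if hits else None

    def taxon_ids(self) -> list[int]:
        return sorted(self._main_by_id)


def load_taxonomy(table_path: str | Path) -> TaxonomyTable:
    """Load the TSV snapshot and build lookup structures."""
    records = []
    with open(table_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"taxon_id", "name", "name_class", "rank", "submittable"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TaxonomyIntegrityError(
                f"{table_path}: expected columns {sorted(required)}"
            )
        for row in reader:
            name_class = row["name_class"].strip().upper()
            rank = row["rank"].strip().upper()
            if name_class not in NAME_CLASSES:
                raise TaxonomyIntegrityError(
                    f"bad name_class {row['name_class']!r}"
                )
            if rank not in RANKS:
                raise TaxonomyIntegrityError(f"bad rank {row['rank']!r}")
            records.append(
                TaxonRecord(
                    taxon_id=int(row["taxon_id"]),
                    name=row["name"].strip(),
                    name_class=name_class,
                    rank=rank,
                    submittable=row["submittable"].strip().lower() == "true",
                )
            )
    return TaxonomyTable(records)


def resolve(scientific_name: str | None, taxon_id: int | str | None,
            table: TaxonomyTable) -> TaxonResolution:
    """Resolve a name and/or taxon id to a curated main name.

    Either input may be absent (``None`` or empty string).  When both
    are given they must designate the same taxon.  Outcomes are
    statuses, never exceptions; precedence when several conditions hold
    is NOT_FOUND > ID_NAME_MISMATCH > NOT_SPECIES_RANK > NOT_SUBMITTABLE
    > SYNONYM_CONVERTED > MAIN_MATCH.
    """
    name = (scientific_name or "").strip()
    tid: int | None = None
    if taxon_id not in (None, ""):
        try:
            tid = int(str(taxon_id).strip())
        except ValueError:
            return TaxonResolution(
                "NOT_FOUND", warnings=[f"TAXON_ID {taxon_id!r} is not an integer"]
            )
    if not name and tid is None:
        return TaxonResolution(
            "NOT_FOUND",
            warnings=["neither SCIENTIFIC_NAME nor TAXON_ID provided"],
        )

    name_rec = table.find_name(name) if name else None
    id_rec = table.main(tid) if tid is not None else None
    if name and name_rec is None:
        return TaxonResolution(
            "NOT_FOUND", warnings=[f"name {name!r} not in taxonomy"]
        )
    if tid is not None and id_rec is None:
        return TaxonResolution(
            "NOT_FOUND", warnings=[f"taxon id {tid} not in taxonomy"]
        )
    if name_rec is not None and id_rec is not None \
            and name_rec.taxon_id != id_rec.taxon_id:
        return TaxonResolution(
            "ID_NAME_MISMATCH",
            warnings=[
                f"name {name!r} belongs to taxon {name_rec.taxon_id}, "
                f"not {id_rec.taxon_id}"
            ],
        )

    resolved = name_rec if name_rec is not None else id_rec
    assert resolved is not None
    main = table.main(resolved.taxon_id)
    assert main is not None
    if main.rank != "SPECIES":
        return TaxonResolution(
            "NOT_SPECIES_RANK",
            warnings=[f"{main.name!r} has rank {main.rank}, not SPECIES"],
        )
    if not main.submittable:
        return TaxonResolution(
            "NOT_SUBMITTABLE",
            warnings=[f"{main.name!r} is not submittable"],
        )
    if name_rec is not None and name_rec.name_class == "SYNONYM":
        return TaxonResolution(
            "SYNONYM_CONVERTED",
            taxon_id=main.taxon_id,
            main_name=main.name,
            warnings=[
                f"{name!r} is a synonym; the main name {main.name!r} "
                "will be stored instead"
            ],
        )
    return TaxonResolution("MAIN_MATCH", taxon_id=main.taxon_id,
                           main_name=main.name)


def reconcile_record(record: ManifestRecord, table: TaxonomyTable):
    """Populate a record's taxonomic fields from the taxonomy.

    Returns ``(updated_record, issues)``.  On a successful resolution
    SCIENTIFIC_NAME and TAXON_ID are filled with the curated values
    (synonym conversion yields a WARNING); any failing status yields an
    ERROR and leaves the record untouched.  Idempotent.
    """
    from .validate import ValidationIssue  # local import: avoid cycle

    res = resolve(record.get("SCIENTIFIC_NAME"), record.get("TAXON_ID"), table)
    issues: list[ValidationIssue] = []
    if res.status in ("MAIN_MATCH", "SYNONYM_CONVERTED"):
        updated = ManifestRecord(
            row_index=record.row_index,
            values={**record.values,
                    "SCIENTIFIC_NAME": res.main_name,
                    "TAXON_ID": str(res.taxon_id)},
            source=record.source,
        )
        if res.status == "SYNONYM_CONVERTED":
            issues.append(ValidationIssue(
                severity="WARNING", code="SYNONYM_CONVERTED",
                row_index=record.row_index, field="SCIENTIFIC_NAME",
                message=res.warnings[0],
            ))
        return updated, issues
    code = {
        "NOT_FOUND": ("TAXON_NOT_FOUND", "SCIENTIFIC_NAME"),
        "ID_NAME_MISMATCH": ("TAXON_ID_NAME_MISMATCH", "TAXON_ID"),
        "NOT_SPECIES_RANK": ("TAXON_NOT_SPECIES_RANK", "SCIENTIFIC_NAME"),
        "NOT_SUBMITTABLE": ("TAXON_NOT_SUBMITTABLE", "SCIENTIFIC_NAME"),
    }[res.status]
    issues.append(ValidationIssue(
        severity="ERROR", code=code[0], row_index=record.row_index,
        field=code[1],
        message="; ".join(res.warnings) or res.status,
    ))
    return record, issues
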