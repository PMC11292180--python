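"""Reading and writing sample manifests.

A manifest is a single-header table (CSV or single-sheet XLSX) whose
columns follow a manifest schema.  Reading normalises headers (case,
alias spellings) and trims cell whitespace but performs no semantic
validation — that is the validation engine's job.  Missing cells become
the empty string; the sentinel tokens ``NOT_COLLECTED``/``NOT_PROVIDED``
are preserved verbatim.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

from .errors import ManifestFormatError
from .schemas import ManifestSchema, canonical_field_name

#: Tokens a submitter may use to mark a value as explicitly missing.
SENTINELS = frozenset({"NOT_COLLECTED", "NOT_PROVIDED"})


@dataclass
class ManifestRecord:
    """One data row: canonical field name -> raw (trimmed) string value."""

    row_index: int
    values: dict[str, str]
    source: str = ""

    def get(self, field: str, default: str = "") -> str:
        return self.values.get(field, default)


@dataclass
class Manifest:
    """An ordered collection of records read against one schema version."""

    schema_version: str
    records: list[ManifestRecord]
    provenance: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def columns(self) -> list[str]:
        return list(self.records[0].values) if self.records else \
            list(self.provenance.get("columns", []))


def _canonicalise_headers(raw_headers: list[str], schema: ManifestSchema):
    """Resolve headers to canonical names; unknown columns keep their
    literal spelling and are reported separately."""
    columns: list[str] = []
    unknown: list[str] = []
    for header in raw_headers:
        canonical = canonical_field_name(header)
        if canonical in schema:
            name = canonical
        else:
            name = header.strip()
            unknown.append(name)
        if name in columns:
            raise ManifestFormatError(
                f"duplicate column {name!r} after header canonicalisation"
            )
        columns.append(name)
    return columns, unknown


def _rows_from_csv(path: Path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8-sig") as fh:
        return [list(row) for row in csv.reader(fh)]


def _rows_from_xlsx(path: Path, sheet: str | None) -> list[list[str]]:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    ws = wb[sheet] if sheet else wb.worksheets[0]
    rows = []
    for row in ws.iter_rows(values_only=True):
        rows.append(["" if cell is None else str(cell) for cell in row])
    wb.close()
    return rows


def read_manifest(path: str | Path, schema: ManifestSchema,
                  sheet: str | None = None) -> Manifest:
    """Read a CSV or XLSX manifest against ``schema``.

    Headers are matched case-insensitively after alias resolution; fully
    blank rows are dropped; values are stripped of surrounding
    whitespace.  ``row_index`` numbers the surviving data rows from 1.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        rows = _rows_from_xlsx(path, sheet)
    else:
        rows = _rows_from_csv(path)
    if not rows or all(not c.strip() for c in rows[0]):
        raise ManifestFormatError(f"{path}: no header row")
    columns, unknown = _canonicalise_headers(rows[0], schema)
    source = f"{path}" + (f"#{sheet}" if sheet else "")
    records: list[ManifestRecord] = []
    for raw in rows[1:]:
        cells = [c.strip() for c in raw]
        if not any(cells):
            continue
        cells += [""] * (len(columns) - len(cells))
        records.append(
            ManifestRecord(
                row_index=len(records) + 1,
                values=dict(zip(columns, cells)),
                source=source,
            )
        )
    return Manifest(
        schema_version=schema.version,
        records=records,
        provenance={
            "source": str(path),
            "sheet": sheet,
            "read_at": datetime.now(timezone.utc).isoformat(),
            "columns": columns,
            "unrecognised_columns": unknown,
        },
    )


def write_manifest(manifest: Manifest, path: str | Path,
                   dialect: str = "csv") -> Path:
    """Write a manifest so that re-reading reproduces records exactly."""
    path = Path(path)
    columns = manifest.columns()
    table = [columns] + [
        [rec.values.get(c, "") for c in columns] for rec in manifest.records
    ]
    if dialect == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerows(table)
    elif dialect == "spreadsheet":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "manifest"
        for row in table:
            ws.append(row)
        wb.save(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def records_to_json(manifest: Manifest) -> dict:
    """JSON-friendly view of a manifest (CLI output)."""
    return {
        "schema_version": manifest.schema_version,
        "provenance": manifest.provenance,
        "records": [
            {"row_index": r.row_index, "values": r.values}
            for r in manifest.records
        ],
    }
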