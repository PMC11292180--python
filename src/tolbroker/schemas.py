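"""Versioned manifest-schema registry.

A manifest schema is the ordered catalogue of fields a collection
manifest must provide: identifiers, taxonomy, collection event data and
project bookkeeping.  Schemas are versioned documents; a core schema can
be widened by taxon-group *extension* schemas (e.g. extra environmental
fields for protists).  Each field carries a controlled vocabulary where
one applies, a visibility flag separating publicly archived metadata
from internal project tracking, and term mappings onto external
standards (Darwin Core, the ENA checklist vocabulary, MIxS).

Bundled schema documents live under ``tolbroker/schemas/`` as YAML, one
file per released version.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ExtensionConflict, SchemaDefinitionError, VersionNotFound

REQUIREMENTS = ("MANDATORY", "OPTIONAL")
VALUE_KINDS = ("FREE_TEXT", "CONTROLLED", "DATE", "DECIMAL", "INTEGER", "IDENTIFIER")
VISIBILITIES = ("PUBLIC", "INTERNAL")
MAPPING_STANDARDS = ("dwc", "ena", "mixs")

#: Header spellings folded onto one canonical field name.
HEADER_ALIASES = {"PLATE_OR_RACK_ID": "RACK_OR_PLATE_ID"}


def canonical_field_name(header: str) -> str:
    """Map a raw column header to its canonical schema field name."""
    name = header.strip().upper()
    return HEADER_ALIASES.get(name, name)


@dataclass(frozen=True)
class FieldSpec:
    """One manifest column: its requirement level, value kind and mappings."""

    name: str
    requirement: str = "OPTIONAL"
    value_kind: str = "FREE_TEXT"
    vocabulary: tuple[str, ...] = ()
    pattern: str | None = None
    visibility: str = "PUBLIC"
    term_mappings: Mapping[str, str] = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.requirement not in REQUIREMENTS:
            raise SchemaDefinitionError(
                f"field {self.name}: unknown requirement {self.requirement!r}"
            )
        if self.value_kind not in VALUE_KINDS:
            raise SchemaDefinitionError(
                f"field {self.name}: unknown value_kind {self.value_kind!r}"
            )
        if self.visibility not in VISIBILITIES:
            raise SchemaDefinitionError(
                f"field {self.name}: unknown visibility {self.visibility!r}"
            )
        if self.value_kind == "CONTROLLED" and not self.vocabulary:
            raise SchemaDefinitionError(
                f"field {self.name}: CONTROLLED field needs a vocabulary"
            )
        if self.value_kind != "CONTROLLED" and self.vocabulary:
            raise SchemaDefinitionError(
                f"field {self.name}: vocabulary given for non-CONTROLLED field"
            )
        if self.pattern is not None:
            try:
                re.compile(self.pattern)
            except re.error as exc:
                raise SchemaDefinitionError(
                    f"field {self.name}: bad pattern {self.pattern!r}: {exc}"
                ) from exc
        for std in self.term_mappings:
            if std not in MAPPING_STANDARDS:
                raise SchemaDefinitionError(
                    f"field {self.name}: unknown mapping standard {std!r}"
                )

    def to_dict(self) -> dict:
        doc: dict = {
            "name": self.name,
            "requirement": self.requirement,
            "value_kind": self.value_kind,
            "visibility": self.visibility,
        }
        if self.vocabulary:
            doc["vocabulary"] = list(self.vocabulary)
        if self.pattern is not None:
            doc["pattern"] = self.pattern
        if self.term_mappings:
            doc["term_mappings"] = dict(self.term_mappings)
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FieldSpec":
        if not isinstance(doc, Mapping) or "name" not in doc:
            raise SchemaDefinitionError(f"malformed field entry: {doc!r}")
        known = {"name", "requirement", "value_kind", "vocabulary",
                 "pattern", "visibility", "term_mappings"}
        extra = set(doc) - known
        if extra:
            raise SchemaDefinitionError(
                f"field {doc['name']}: unknown keys {sorted(extra)}"
            )
        return cls(
            name=str(doc["name"]),
            requirement=doc.get("requirement", "OPTIONAL"),
            value_kind=doc.get("value_kind", "FREE_TEXT"),
            vocabulary=tuple(str(v) for v in doc.get("vocabulary", ())),
            pattern=doc.get("pattern"),
            visibility=doc.get("visibility", "PUBLIC"),
            term_mappings=dict(doc.get("term_mappings", {})),
        )


def parse_version(version: str) -> tuple[int, ...]:
    """Parse a dotted version string into an orderable tuple."""
    try:
        return tuple(int(p) for p in str(version).split("."))
    except ValueError as exc:
        raise SchemaDefinitionError(f"unparseable version {version!r}") from exc


@dataclass(frozen=True)
class ManifestSchema:
    """An ordered, versioned catalogue of :class:`FieldSpec`."""

    name: str
    version: str
    fields: tuple[FieldSpec, ...]
    extensions_applied: tuple[str, ...] = ()

    def __post_init__(self):
        parse_version(self.version)
        seen: set[str] = set()
        for f in self.fields:
            if f.name in seen:
                raise SchemaDefinitionError(f"duplicate field name {f.name}")
            seen.add(f.name)

    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.fields)

    def __getitem__(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def get(self, name: str) -> FieldSpec | None:
        return self[name] if name in self else None

    def to_dict(self) -> dict:
        doc: dict = {
            "name": self.name,
            "version": self.version,
            "fields": [f.to_dict() for f in self.fields],
        }
        if self.extensions_applied:
            doc["extensions_applied"] = list(self.extensions_applied)
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ManifestSchema":
        if not isinstance(doc, Mapping):
            raise SchemaDefinitionError("schema document is not a mapping")
        for key in ("name", "version"):
            if key not in doc:
                raise SchemaDefinitionError(f"schema document lacks {key!r}")
        return cls(
            name=str(doc["name"]),
            version=str(doc["version"]),
            fields=tuple(FieldSpec.from_dict(f) for f in doc.get("fields", ())),
            extensions_applied=tuple(doc.get("extensions_applied", ())),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )


def _registry_dir():
    return resources.files("tolbroker") / "schemas"


def available_versions(name: str) -> list[str]:
    """Versions of a bundled schema, ascending."""
    versions = []
    for entry in _registry_dir().iterdir():
        fname = entry.name
        if fname.endswith(".yaml") and fname.startswith(name + "-"):
            versions.append(fname[len(name) + 1 : -len(".yaml")])
    return sorted(versions, key=parse_version)


def load_schema(name: str | Path, version: str = "latest") -> ManifestSchema:
    """Load a schema by registry name (e.g. ``"dtol-core"``) or file path.

    ``version`` selects a bundled release; ``"latest"`` picks the highest.
    A path argument loads that document directly and ignores ``version``.
    """
    path = Path(name)
    if path.suffix in {".yaml", ".yml"} or path.is_file():
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
        return ManifestSchema.from_dict(doc)
    versions = available_versions(str(name))
    if not versions:
        raise VersionNotFound(f"no bundled schema named {name!r}")
    if version == "latest":
        version = versions[-1]
    if version not in versions:
        raise VersionNotFound(
            f"schema {name!r} has no version {version!r}; available: {versions}"
        )
    text = (_registry_dir() / f"{name}-{version}.yaml").read_text(encoding="utf-8")
    schema = ManifestSchema.from_dict(yaml.safe_load(text))
    if schema.version != version:
        raise SchemaDefinitionError(
            f"document for {name}-{version} declares version {schema.version}"
        )
    return schema


def merge_extension(core: ManifestSchema, extension: ManifestSchema) -> ManifestSchema:
    """Append a taxon-group extension to a core schema.

    Extension fields come after the core fields in manifest column order.
    An extension entry naming an existing core field may only *tighten*
    it (shrink the vocabulary, or promote OPTIONAL to MANDATORY); any
    change of value kind, demotion of a MANDATORY field, or vocabulary
    widening is a conflict.
    """
    merged: list[FieldSpec] = []
    ext_by_name = {f.name: f for f in extension.fields}
    for f in core.fields:
        override = ext_by_name.pop(f.name, None)
        if override is None:
            merged.append(f)
            continue
        if override.value_kind != f.value_kind:
            raise ExtensionConflict(
                f"extension {extension.name} redefines {f.name} as "
                f"{override.value_kind} (core: {f.value_kind})"
            )
        if f.requirement == "MANDATORY" and override.requirement == "OPTIONAL":
            raise ExtensionConflict(
                f"extension {extension.name} demotes mandatory field {f.name}"
            )
        if override.vocabulary and not set(override.vocabulary) <= set(f.vocabulary):
            raise ExtensionConflict(
                f"extension {extension.name} widens vocabulary of {f.name}"
            )
        merged.append(override)
    merged.extend(ext_by_name[f.name] for f in extension.fields
                  if f.name in ext_by_name)
    return ManifestSchema(
        name=core.name,
        version=core.version,
        fields=tuple(merged),
        extensions_applied=core.extensions_applied + (extension.name,),
    )


def checklist_subset(schema: ManifestSchema) -> list[FieldSpec]:
    """Fields projected into the public archive checklist.

    Internal project-tracking fields are excluded; order is preserved.
    """
    return [f for f in schema.fields if f.visibility == "PUBLIC"]
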