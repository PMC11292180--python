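"""Projections into external standard representations.

* ENA sample XML (``SAMPLE_SET``/``SAMPLE``) carrying the public
  checklist subset plus the specimen/sample relationship attributes;
* Darwin Core term-mapped occurrence views;
* MIxS term-mapped views (minimal bundled map);
* the broker's own full JSON ("tol") view with accessions and the
  manifest version each sample was submitted under.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

from lxml import etree

from .errors import ExportError
from .graph import EDGE_TAGS, SampleGraph
from .manifest import ManifestRecord
from .schemas import ManifestSchema, checklist_subset

#: Checklist and umbrella-study accessions used in exports.
TOL_CHECKLIST_ACCESSION = "ERC000053"
DEFAULT_STUDY_ACCESSION = "PRJEB40665"

EXPORT_FORMATS = ("tol", "ena", "mixs", "dwc")


@dataclass(frozen=True)
class ExportProfile:
    format: str = "tol"
    checklist_accession: str = TOL_CHECKLIST_ACCESSION
    study_accession: str = DEFAULT_STUDY_ACCESSION

    def __post_init__(self):
        if self.format not in EXPORT_FORMATS:
            raise ExportError(f"unknown export format {self.format!r}")


def _add_attribute(attrs: etree._Element, tag: str, value: str) -> None:
    attr = etree.SubElement(attrs, "SAMPLE_ATTRIBUTE")
    etree.SubElement(attr, "TAG").text = tag
    etree.SubElement(attr, "VALUE").text = value


def _sample_element(root, node, schema_public, profile,
                    relationship=None, accessions=None):
    sample = etree.SubElement(root, "SAMPLE", alias=node.identifier)
    if accessions:
        sample.set("accession", accessions)
    taxon_id = node.metadata.get("TAXON_ID", "")
    if not taxon_id:
        raise ExportError(f"node {node.identifier} lacks a TAXON_ID")
    name_el = etree.SubElement(sample, "SAMPLE_NAME")
    etree.SubElement(name_el, "TAXON_ID").text = str(taxon_id)
    scientific = node.metadata.get("SCIENTIFIC_NAME", "")
    if scientific:
        etree.SubElement(name_el, "SCIENTIFIC_NAME").text = scientific
    attrs = etree.SubElement(sample, "SAMPLE_ATTRIBUTES")
    for spec in schema_public:
        value = node.metadata.get(spec.name, "")
        if value:
            _add_attribute(attrs, spec.name, value)
    if relationship is not None:
        _add_attribute(attrs, EDGE_TAGS[relationship[0]], relationship[1])
    _add_attribute(attrs, "ENA-CHECKLIST", profile.checklist_accession)
    return sample


def to_ena_xml(graph: SampleGraph, schema: ManifestSchema,
               profile: ExportProfile | None = None,
               accessions: dict | None = None) -> etree._Element:
    """Render a graph as an ENA sample-submission XML document.

    Specimen-level samples come first so child samples can reference
    their parent by alias before any accession exists; ``accessions``
    optionally maps node identifiers to already-minted BioSample
    accessions, which are then preferred as relationship targets.
    """
    profile = profile or ExportProfile(format="ena")
    if profile.format != "ena":
        raise ExportError(f"to_ena_xml needs an ena profile, got "
                          f"{profile.format!r}")
    accessions = accessions or {}
    public = checklist_subset(schema)
    root = etree.Element("SAMPLE_SET")
    for node in graph.specimen_nodes():
        _sample_element(root, node, public, profile,
                        accessions=accessions.get(node.identifier))
    parent_of = {id(e.child): e for e in graph.edges}
    for node in graph.sample_nodes():
        edge = parent_of.get(id(node))
        if edge is None:
            raise ExportError(f"sample node {node.identifier} has no edge")
        target = accessions.get(edge.parent.identifier,
                                edge.parent.identifier)
        _sample_element(root, node, public, profile,
                        relationship=(edge.kind, target),
                        accessions=accessions.get(node.identifier))
    return root


def ena_xml_bytes(graph: SampleGraph, schema: ManifestSchema,
                  profile: ExportProfile | None = None,
                  accessions: dict | None = None) -> bytes:
    return etree.tostring(
        to_ena_xml(graph, schema, profile, accessions),
        pretty_print=True, xml_declaration=True, encoding="UTF-8",
    )


def _term_mapped(record_values: dict, schema: ManifestSchema,
                 standard: str) -> dict:
    out = {}
    for spec in schema.fields:
        term = spec.term_mappings.get(standard)
        value = record_values.get(spec.name, "")
        if term and value:
            out[term] = value
    return out


def to_darwin_core(records: list[ManifestRecord],
                   schema: ManifestSchema) -> list[dict]:
    """Map each record onto Darwin Core terms; unmapped fields are
    omitted.  Pure per-record function."""
    return [_term_mapped(r.values, schema, "dwc") for r in records]


def to_mixs(records: list[ManifestRecord],
            schema: ManifestSchema) -> list[dict]:
    """Minimal MIxS term-mapped view (collection date, location)."""
    return [_term_mapped(r.values, schema, "mixs") for r in records]


def export_samples(broker_records, profile: ExportProfile,
                   schema_loader=None) -> str:
    """Serialise broker records in the requested standard as JSON.

    ``tol`` returns everything the broker knows (metadata, state,
    accessions, ToLID, manifest schema version); ``ena`` restricts
    metadata to the public checklist subset; ``dwc``/``mixs`` return
    term-mapped views.  Every output record carries its
    ``schema_version`` so consumers can tell which fields to expect.
    """
    from .schemas import load_schema

    loader = schema_loader or (lambda v: load_schema("dtol-core", v))
    out = []
    for rec in broker_records:
        schema = loader(rec.schema_version)
        base = {
            "sample_key": rec.sample_key,
            "specimen_id": rec.specimen_id,
            "schema_version": rec.schema_version,
        }
        if profile.format == "tol":
            base.update(
                state=rec.state,
                biosample_accession=rec.biosample_accession,
                ena_accession=rec.ena_accession,
                tolid=rec.tolid,
                profile=rec.profile,
                study_accession=profile.study_accession,
                metadata=dict(rec.metadata),
            )
        elif profile.format == "ena":
            public = {s.name for s in checklist_subset(schema)}
            base.update(
                biosample_accession=rec.biosample_accession,
                ena_accession=rec.ena_accession,
                checklist=profile.checklist_accession,
                metadata={k: v for k, v in rec.metadata.items()
                          if k in public},
            )
        elif profile.format == "dwc":
            base["metadata"] = _term_mapped(rec.metadata, schema, "dwc")
        elif profile.format == "mixs":
            base["metadata"] = _term_mapped(rec.metadata, schema, "mixs")
        else:  # pragma: no cover - ExportProfile already rejects
            raise ExportError(f"unknown export format {profile.format!r}")
        out.append(base)
    return json.dumps(out, indent=2, sort_keys=True)
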