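"""Synthetic taxonomies and manifests with ground-truth error injection.

Everything any other module needs for testing is generated here, with
no downloads: a taxonomy snapshot with synonyms, ranks and
submittability flags; manifests that pass validation cleanly; and a
corrupter that plants specific rule violations and returns a
machine-readable :class:`InjectionLog` — the oracle the validation
engine is measured against.

Synthetic binomials are assembled from syllable tables and taxon ids
start at 9,000,000, so nothing here collides with a real taxonomy.
All generators are pure functions of (parameters, seed).
"""
from __future__ import annotations

import csv
import json
import math
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .errors import FixtureConfigError
from .manifest import Manifest, ManifestRecord, read_manifest, write_manifest
from .schemas import ManifestSchema
from .taxonomy import TaxonomyTable, load_taxonomy
from .validate import RULE_CATALOGUE, TAXONOMY_ERROR_CODES

_SYLLABLES = ["ba", "ce", "di", "fo", "gu", "la", "me", "ni", "po", "ra",
              "su", "te", "vi", "xo", "zu"]
_EPITHET_SUFFIXES = ["us", "a", "um", "ensis", "icus", "oides"]
_LOCATIONS = ["United Kingdom | Norfolk", "United Kingdom | Oxfordshire",
              "Ireland | Galway", "United Kingdom | Highlands",
              "United Kingdom | Pembrokeshire"]
_GALS = ["SANGER INSTITUTE", "MARINE BIOLOGICAL ASSOCIATION",
         "ROYAL BOTANIC GARDEN EDINBURGH", "UNIVERSITY OF OXFORD"]
_PARTS = ["HEAD", "THORAX", "ABDOMEN", "LEG", "BLOOD", "MUSCLE"]
_SEXES = ["MALE", "FEMALE", "HERMAPHRODITE", "UNKNOWN"]
_LIFESTAGES = ["ADULT", "JUVENILE", "LARVA"]
_PRESERVATION = ["SNAP_FROZEN", "ETHANOL", "DRY_ICE"]
_COLLECTORS = ["A. Collector", "B. Fieldworker", "C. Naturalist"]

#: First synthetic taxon id; far above anything in use.
TAXON_ID_BASE = 9_000_000

#: Codes only detectable after the taxonomy phase passes.
POST_TAXONOMY_CODES = RULE_CATALOGUE - TAXONOMY_ERROR_CODES - {
    "SYNONYM_CONVERTED"}

#: Codes whose injection touches two manifest rows.
TWO_ROW_CODES = frozenset({
    "SPECIMEN_TAXON_CONFLICT", "DUPLICATE_WHOLE_ORGANISM",
    "DUPLICATE_SAMPLE_ID",
})


@dataclass
class InjectionLog:
    """Ground truth for a corrupted manifest: the exact (code,
    row_index, field) issues validation must report."""

    seed: int
    entries: list[tuple[str, int, str]] = dc_field(default_factory=list)

    def add(self, code: str, row_index: int, field: str) -> None:
        assert code in RULE_CATALOGUE, code
        self.entries.append((code, row_index, field))

    def as_multiset(self) -> dict[tuple[str, int, str], int]:
        counts: dict[tuple[str, int, str], int] = {}
        for entry in self.entries:
            counts[entry] = counts.get(entry, 0) + 1
        return counts

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed,
             "entries": [
                 {"code": c, "row_index": r, "field": f}
                 for c, r, f in self.entries]},
            indent=2)


def _binomial(rng: random.Random, used: set[str]) -> str:
    while True:
        genus = "".join(rng.choices(_SYLLABLES, k=3)).capitalize()
        epithet = ("".join(rng.choices(_SYLLABLES, k=2))
                   + rng.choice(_EPITHET_SUFFIXES))
        name = f"{genus} {epithet}"
        if name not in used:
            used.add(name)
            return name


def generate_taxonomy(n_species: int, synonym_fraction: float = 0.25,
                      nonsubmittable_fraction: float = 0.1,
                      seed: int = 0,
                      out_path: str | Path = "taxonomy.tsv") -> Path:
    """Write a synthetic taxonomy TSV.

    Produces ``n_species`` species-rank MAIN records plus
    ``ceil(synonym_fraction * n)`` synonym rows, genus-rank parent
    records, and a non-submittable flag on the stated fraction of
    species.  Byte-identical for identical parameters and seed.
    """
    if n_species < 0:
        raise FixtureConfigError("n_species must be >= 0")
    for frac in (synonym_fraction, nonsubmittable_fraction):
        if not 0 <= frac <= 1:
            raise FixtureConfigError("fractions must lie in [0, 1]")
    rng = random.Random(seed)
    used_names: set[str] = set()
    rows = []
    next_id = TAXON_ID_BASE
    species_names = [_binomial(rng, used_names) for _ in range(n_species)]
    n_nonsub = math.ceil(nonsubmittable_fraction * n_species)
    n_syn = math.ceil(synonym_fraction * n_species)
    nonsub = set(rng.sample(range(n_species), n_nonsub)) if n_species else set()
    with_syn = set(rng.sample(range(n_species), n_syn)) if n_species else set()
    genera: dict[str, int] = {}
    for i, name in enumerate(species_names):
        tid = next_id
        next_id += 1
        rows.append((tid, name, "MAIN", "SPECIES",
                     "false" if i in nonsub else "true"))
        if i in with_syn:
            rows.append((tid, _binomial(rng, used_names), "SYNONYM",
                         "SPECIES", "false" if i in nonsub else "true"))
        genera.setdefault(name.split()[0], 0)
    for genus in sorted(genera):
        rows.append((next_id, genus, "MAIN", "GENUS", "false"))
        next_id += 1
    out_path = Path(out_path)
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["taxon_id", "name", "name_class", "rank",
                         "submittable"])
        writer.writerows(rows)
    return out_path


def _species_pool(taxonomy: TaxonomyTable):
    """Submittable species-rank main names usable in clean manifests."""
    return [rec for tid in taxonomy.taxon_ids()
            for rec in [taxonomy.main(tid)]
            if rec.rank == "SPECIES" and rec.submittable]


def generate_manifest(n_rows: int, taxonomy: TaxonomyTable,
                      schema: ManifestSchema,
                      specimen_sharing: float = 0.2,
                      whole_organism_fraction: float = 0.25,
                      symbiont_fraction: float = 0.0,
                      seed: int = 0,
                      out_path: str | Path = "manifest.csv") -> Path:
    """Write a manifest that passes validation with zero errors.

    ``specimen_sharing`` is the probability a row reuses an existing
    (non whole-organism) specimen, with consistent taxonomy and a
    distinct organism part per tube; ``whole_organism_fraction`` is the
    chance a *new* specimen is collected whole (and therefore never
    shared); ``symbiont_fraction`` flags that share of non-whole rows
    as symbionts.  Deterministic per seed.
    """
    if n_rows > 0 and len(_species_pool(taxonomy)) == 0:
        raise FixtureConfigError("taxonomy has no usable species")
    if specimen_sharing >= 1 and (whole_organism_fraction > 0 or n_rows > 0):
        raise FixtureConfigError(
            "specimen_sharing = 1 leaves no row able to start a specimen")
    rng = random.Random(seed)
    pool = _species_pool(taxonomy)
    columns = schema.field_names()
    shareable: list[dict] = []   # specimen contexts open for reuse
    records: list[ManifestRecord] = []
    for i in range(n_rows):
        reuse = shareable and rng.random() < specimen_sharing
        if reuse:
            ctx = rng.choice(shareable)
            whole = False
        else:
            sp = rng.choice(pool)
            ctx = {
                "specimen_id": f"SPEC{seed % 1000:03d}{len(shareable) + i:04d}",
                "taxon": sp,
                "env_sample_id": f"ENV{i + 1:04d}",
            }
            whole = rng.random() < whole_organism_fraction
            if not whole:
                shareable.append(ctx)
        part = "WHOLE_ORGANISM" if whole else rng.choice(_PARTS)
        symbiont = (not whole) and rng.random() < symbiont_fraction
        values = {c: "" for c in columns}
        values.update({
            "SERIES": str(i + 1),
            "RACK_OR_PLATE_ID": f"RK{seed % 1000:03d}{i // 24:02d}",
            "TUBE_OR_WELL_ID": f"TB{i + 1:04d}",
            "SPECIMEN_ID": ctx["specimen_id"],
            "ENV_SAMPLE_ID": ctx["env_sample_id"],
            "SCIENTIFIC_NAME": ctx["taxon"].name,
            "TAXON_ID": str(ctx["taxon"].taxon_id),
            "ORGANISM_PART": part,
            "SYMBIONT": "SYMBIONT" if symbiont else "TARGET",
            "LIFESTAGE": rng.choice(_LIFESTAGES),
            "SEX": rng.choice(_SEXES),
            "DATE_OF_COLLECTION": (
                f"{rng.randint(2020, 2023)}-{rng.randint(1, 12):02d}-"
                f"{rng.randint(1, 28):02d}"),
            "COLLECTION_LOCATION": rng.choice(_LOCATIONS),
            "DECIMAL_LATITUDE": f"{rng.uniform(49.9, 58.6):.4f}",
            "DECIMAL_LONGITUDE": f"{rng.uniform(-10.5, 1.7):.4f}",
            "COLLECTED_BY": rng.choice(_COLLECTORS),
            "COLLECTION_EVENT": f"EVT{i + 1:04d}",
            "IDENTIFIED_BY": rng.choice(_COLLECTORS),
            "IDENTIFICATION_UNCERTAINTY": "",
            "HAZARD_GROUP": "HG1",
            "PRESERVATION_APPROACH": rng.choice(_PRESERVATION),
            "VOUCHER_ID": f"VCH{i + 1:04d}",
            "REGULATORY_COMPLIANCE": "Y",
            "GAL": rng.choice(_GALS),
        })
        values = {c: values.get(c, "") for c in columns}
        records.append(ManifestRecord(row_index=i + 1, values=values))
    manifest = Manifest(schema_version=schema.version, records=records,
                        provenance={"columns": columns})
    return write_manifest(manifest, out_path)


class _Injector:
    """Plants one kind of violation into rows not touched by any other
    injection, recording the exact issues validation must raise."""

    def __init__(self, manifest: Manifest, taxonomy: TaxonomyTable,
                 rng: random.Random, log: InjectionLog):
        self.manifest = manifest
        self.taxonomy = taxonomy
        self.rng = rng
        self.log = log
        self.used_rows: set[int] = set()
        counts: dict[str, int] = {}
        for rec in manifest.records:
            spid = rec.get("SPECIMEN_ID")
            counts[spid] = counts.get(spid, 0) + 1
        self._singleton = {
            r.row_index for r in manifest.records
            if counts[r.get("SPECIMEN_ID")] == 1
        }

    def _take_rows(self, n: int, singleton: bool = False,
                   not_whole: bool = False) -> list[ManifestRecord]:
        candidates = []
        for rec in self.manifest.records:
            if rec.row_index in self.used_rows:
                continue
            if singleton and rec.row_index not in self._singleton:
                continue
            if not_whole and rec.get("ORGANISM_PART") == "WHOLE_ORGANISM":
                continue
            candidates.append(rec)
        if len(candidates) < n:
            raise FixtureConfigError(
                f"not enough eligible rows ({len(candidates)} < {n})")
        chosen = self.rng.sample(candidates, n)
        self.used_rows.update(r.row_index for r in chosen)
        return chosen

    def _other_species(self, exclude_id: str):
        pool = [rec for rec in _species_pool(self.taxonomy)
                if str(rec.taxon_id) != exclude_id]
        if not pool:
            raise FixtureConfigError("taxonomy too small for injection")
        return self.rng.choice(pool)

    # One method per rule code -------------------------------------------

    def inject_synonym_converted(self):
        synonyms = [r for r in self.taxonomy.records
                    if r.name_class == "SYNONYM" and r.submittable]
        if not synonyms:
            raise FixtureConfigError("taxonomy has no submittable synonyms")
        (row,) = self._take_rows(1, singleton=True)
        syn = self.rng.choice(synonyms)
        row.values["SCIENTIFIC_NAME"] = syn.name
        row.values["TAXON_ID"] = str(syn.taxon_id)
        self.log.add("SYNONYM_CONVERTED", row.row_index, "SCIENTIFIC_NAME")

    def inject_taxon_not_found(self):
        (row,) = self._take_rows(1, singleton=True)
        name = "Imaginarius absentus"
        assert self.taxonomy.find_name(name) is None
        row.values["SCIENTIFIC_NAME"] = name
        row.values["TAXON_ID"] = ""
        self.log.add("TAXON_NOT_FOUND", row.row_index, "SCIENTIFIC_NAME")

    def inject_taxon_not_submittable(self):
        bad = [rec for tid in self.taxonomy.taxon_ids()
               for rec in [self.taxonomy.main(tid)]
               if rec.rank == "SPECIES" and not rec.submittable]
        if not bad:
            raise FixtureConfigError("taxonomy has no non-submittable species")
        (row,) = self._take_rows(1, singleton=True)
        rec = self.rng.choice(bad)
        row.values["SCIENTIFIC_NAME"] = rec.name
        row.values["TAXON_ID"] = str(rec.taxon_id)
        self.log.add("TAXON_NOT_SUBMITTABLE", row.row_index,
                     "SCIENTIFIC_NAME")

    def inject_taxon_not_species_rank(self):
        genera = [rec for tid in self.taxonomy.taxon_ids()
                  for rec in [self.taxonomy.main(tid)]
                  if rec.rank != "SPECIES"]
        if not genera:
            raise FixtureConfigError("taxonomy has no higher-rank records")
        (row,) = self._take_rows(1, singleton=True)
        rec = self.rng.choice(genera)
        row.values["SCIENTIFIC_NAME"] = rec.name
        row.values["TAXON_ID"] = str(rec.taxon_id)
        self.log.add("TAXON_NOT_SPECIES_RANK", row.row_index,
                     "SCIENTIFIC_NAME")

    def inject_taxon_id_name_mismatch(self):
        (row,) = self._take_rows(1, singleton=True)
        other = self._other_species(row.get("TAXON_ID"))
        row.values["TAXON_ID"] = str(other.taxon_id)
        self.log.add("TAXON_ID_NAME_MISMATCH", row.row_index, "TAXON_ID")

    def inject_missing_mandatory(self):
        (row,) = self._take_rows(1)
        field = self.rng.choice(["COLLECTION_LOCATION", "GAL", "SEX"])
        row.values[field] = ""
        self.log.add("MISSING_MANDATORY", row.row_index, field)

    def inject_vocab_violation(self):
        (row,) = self._take_rows(1)
        row.values["SEX"] = self.rng.choice(["Fem", "F", "f", "girl"])
        self.log.add("VOCAB_VIOLATION", row.row_index, "SEX")

    def inject_bad_date(self):
        (row,) = self._take_rows(1)
        row.values["DATE_OF_COLLECTION"] = self.rng.choice(
            ["31/12/2021", "2021-02-30", "May 2021"])
        self.log.add("BAD_DATE", row.row_index, "DATE_OF_COLLECTION")

    def inject_partial_date(self):
        (row,) = self._take_rows(1)
        row.values["DATE_OF_COLLECTION"] = self.rng.choice(["2021", "2021-05"])
        self.log.add("PARTIAL_DATE", row.row_index, "DATE_OF_COLLECTION")

    def inject_bad_coordinate(self):
        (row,) = self._take_rows(1)
        row.values["DECIMAL_LATITUDE"] = self.rng.choice(
            ["95.0", "-90.5", "north"])
        self.log.add("BAD_COORDINATE", row.row_index, "DECIMAL_LATITUDE")

    def inject_nonstandard_tube_id(self):
        (row,) = self._take_rows(1)
        row.values["TUBE_OR_WELL_ID"] = f"weird id {row.row_index}!"
        self.log.add("NONSTANDARD_TUBE_ID", row.row_index, "TUBE_OR_WELL_ID")

    def inject_specimen_taxon_conflict(self):
        a, b = self._take_rows(2, singleton=True, not_whole=True)
        b.values["SPECIMEN_ID"] = a.get("SPECIMEN_ID")
        if b.get("TAXON_ID") == a.get("TAXON_ID"):
            other = self._other_species(a.get("TAXON_ID"))
            b.values["SCIENTIFIC_NAME"] = other.name
            b.values["TAXON_ID"] = str(other.taxon_id)
        for row in (a, b):
            self.log.add("SPECIMEN_TAXON_CONFLICT", row.row_index,
                         "SPECIMEN_ID")

    def inject_duplicate_whole_organism(self):
        a, b = self._take_rows(2, singleton=True, not_whole=True)
        b.values["SPECIMEN_ID"] = a.get("SPECIMEN_ID")
        b.values["SCIENTIFIC_NAME"] = a.get("SCIENTIFIC_NAME")
        b.values["TAXON_ID"] = a.get("TAXON_ID")
        a.values["ORGANISM_PART"] = "WHOLE_ORGANISM"
        for row in (a, b):
            self.log.add("DUPLICATE_WHOLE_ORGANISM", row.row_index,
                         "SPECIMEN_ID")

    def inject_duplicate_sample_id(self):
        a, b = self._take_rows(2)
        b.values["RACK_OR_PLATE_ID"] = a.get("RACK_OR_PLATE_ID")
        b.values["TUBE_OR_WELL_ID"] = a.get("TUBE_OR_WELL_ID")
        for row in (a, b):
            self.log.add("DUPLICATE_SAMPLE_ID", row.row_index,
                         "TUBE_OR_WELL_ID")


def inject_errors(manifest_path: str | Path, rules: list[tuple[str, int]],
                  taxonomy: TaxonomyTable, schema: ManifestSchema,
                  seed: int = 0,
                  out_path: str | Path = "corrupted.csv"
                  ) -> tuple[Path, InjectionLog]:
    """Corrupt a clean manifest with the requested rule violations.

    Each (code, count) pair plants ``count`` independent violations in
    rows no other injection touches, so no injection masks another.
    Because a taxonomy ERROR aborts the field and cross phases, mixing a
    taxonomy-error code with a later-phase code in one manifest would
    hide the latter; such requests are refused.
    """
    codes = [code for code, count in rules for _ in range(count)]
    unknown = set(codes) - RULE_CATALOGUE
    if unknown:
        raise FixtureConfigError(f"unknown rule codes {sorted(unknown)}")
    if set(codes) & TAXONOMY_ERROR_CODES and set(codes) & POST_TAXONOMY_CODES:
        raise FixtureConfigError(
            "taxonomy-error injections would mask field/cross injections")
    manifest = read_manifest(manifest_path, schema)
    rng = random.Random(seed)
    log = InjectionLog(seed=seed)
    injector = _Injector(manifest, taxonomy, rng, log)
    for code in codes:
        getattr(injector, f"inject_{code.lower()}")()
    write_manifest(manifest, out_path)
    return Path(out_path), log


def load_injection_log(path: str | Path) -> InjectionLog:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    log = InjectionLog(seed=doc["seed"])
    for entry in doc["entries"]:
        log.add(entry["code"], entry["row_index"], entry["field"])
    return log
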