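# Methods

## The brokering model

`tolbroker` models the journey of sample metadata in a large
biodiversity sequencing programme: a collector at a Genome Acquisition
Laboratory (GAL) fills a tabular manifest, a validation engine checks
it, a human supervisor accepts or rejects the pending samples, and
accepted samples are registered — one public BioSample per sample *and*
one per specimen — with relationship links between them. The unit of
identity is deliberate: a **specimen** is one genetic individual
(SPECIMEN_ID, assigned by the GAL); a **sample** is material from it in
one container, identified by the concatenation
`RACK_OR_PLATE_ID + "/" + TUBE_OR_WELL_ID`. Multiple samples may derive
from one specimen (insect blood in one tube, a leg in another), which
is why cross-row rules and the relationship graph exist at all.

## Schemas and versioning

A manifest schema is an ordered field catalogue; order is the column
order of the spreadsheet. Each field carries a requirement level
(MANDATORY/OPTIONAL — finer gradations used operationally are collapsed
to these two), a value kind (FREE_TEXT, CONTROLLED, DATE, DECIMAL,
INTEGER, IDENTIFIER), an optional vocabulary or regex pattern, a
PUBLIC/INTERNAL visibility flag, and term mappings onto Darwin Core,
the ENA checklist vocabulary and MIxS. Schemas are YAML documents
bundled with the package, one per released version; versions are dotted
integers with total order and `latest` resolution. The bundled
`dtol-core` catalogue contains the canonical identifier/taxonomy/
collection fields plus one representative field per property class
(lifestage, hazard group, preservation, voucher, collector, collection
event, identification uncertainty, regulatory compliance, GAL); it is a
representative core, not a reconstruction of the full 50+ field
operational SOP. Versions 2.4.0 and 2.4.1 differ by one field
(VOUCHER_ID) to exercise version-aware behaviour. `PLATE_OR_RACK_ID`
is accepted as a header alias of the canonical `RACK_OR_PLATE_ID`,
since both spellings circulate.

Extensions append taxon-group fields after the core (the bundled
protist extension adds SALINITY, WATER_TEMPERATURE, PH, all optional
DECIMAL). An extension may tighten a core field (shrink its vocabulary,
promote OPTIONAL to MANDATORY) but never change its value kind, demote
a mandatory field, or widen a vocabulary.

## Taxonomy resolution

Names must resolve at species rank against a *pinned local snapshot* in
TSV form (`taxon_id, name, name_class, rank, submittable`). A live
taxonomy service changes often enough to flip a previously valid
manifest, so the snapshot is the unit of reproducibility; a live client
can implement the same lookup surface. Matching is case-insensitive and
exact (no fuzzy matching). Either SCIENTIFIC_NAME or TAXON_ID suffices;
given both they must agree. Synonyms convert to the main name with a
warning — the curated name is what gets stored. Outcome precedence when
several conditions hold: NOT_FOUND > ID_NAME_MISMATCH >
NOT_SPECIES_RANK > NOT_SUBMITTABLE > SYNONYM_CONVERTED > MAIN_MATCH.
Rank is collapsed to SPECIES/GENUS/FAMILY/OTHER and only SPECIES
passes; subspecies handling is out of scope.

## Validation

Three phases, in order:

1. **Taxonomy** — every row is reconciled as above; taxonomic fields
   are populated from the snapshot. Any taxonomy ERROR aborts the later
   phases (submission stops), though the phase itself always processes
   all rows.
2. **Field** — per cell: missing mandatory values (the sentinels
   `NOT_COLLECTED`/`NOT_PROVIDED` count as missing unless the field's
   vocabulary lists them or the field is a DATE, where verbatim capture
   admits them); controlled vocabulary after case-folding; dates in
   ISO-8601 `YYYY-MM-DD` (partial `YYYY` or `YYYY-MM` is a warning,
   anything else an error); latitude in [-90, 90] and longitude in
   [-180, 180]; tube/well ids against the configurable barcode pattern
   `^[A-Za-z0-9]+$` — a warning, because unusual barcodes are worth a
   second look but not necessarily wrong. Other DECIMAL/INTEGER fields
   are passed through: TAXON_ID integrity belongs to the taxonomy
   phase, and the issue catalogue is deliberately closed.
3. **Cross** — within the manifest: one specimen, one taxon (error on
   every row of the offending group); a specimen appearing in more than
   one row while any of them is `WHOLE_ORGANISM` (an entire individual
   cannot occupy two tubes); duplicate rack+tube pairs. Against the
   broker store, a specimen previously registered under a different
   taxon is also a conflict.

Issues carry a severity, a stable code from the 14-code catalogue, the
row and field, and are sorted by (row, field, code); a report passes iff
it contains no ERROR. Field and cross phases are not mutually gating so
a submitter sees all remaining problems at once. Free-text
COLLECTION_LOCATION is never cross-checked against coordinates —
ambiguity there is resolved by the schema having distinct fields, not
by validation heuristics.

## The relationship graph

One specimen-level node per distinct SPECIMEN_ID; one sample-level node
per row; exactly one edge per sample: `SAMPLE_SYMBIONT_OF` when the
configured symbiont flag field (default `SYMBIONT`, vocabulary
TARGET/SYMBIONT) says so, `SAME_AS` for whole organisms, otherwise
`SAMPLE_DERIVED_FROM`. SAME_AS is 1:1; the other kinds are many:1.
`check_graph` re-derives every invariant by brute force and is used
both as a defence-in-depth check after construction and as the
detection oracle in mutation tests. ENV_SAMPLE_ID (environmental or
cultured source, e.g. a protist culture) is carried as node metadata
rather than as a node of its own — the derived single-cell samples
refer to it alongside the SPECIMEN_ID, and no distinct edge type is
defined for it.

## Exports

ENA sample XML emits one `SAMPLE` element per node, specimen-level
first so children can reference parents by alias before accessioning
(minted accessions are preferred once they exist). Attributes are
exactly the PUBLIC checklist subset plus `ENA-CHECKLIST = ERC000053`
and, on child samples, one relationship attribute whose tag is the
spaced lowercase edge kind ("sample same as", "sample derived from",
"sample symbiont of") — relationship-as-attribute is the archive's
convention. Darwin Core and MIxS exports are pure per-record term
projections (unmapped or empty fields omitted); the MIxS map is
deliberately minimal (collection date, location, the protist
environmental fields). The JSON ("tol") view returns everything,
always including the schema version a sample was submitted under, so
consumers know which fields to expect.

## Lifecycle, accessions, audit

States move only along PENDING→ACCEPTED, PENDING→REJECTED and
ACCEPTED→SUBMITTED. Submission requires the SAMPLE_SUBMITTER role and a
passing report; review requires SAMPLE_SUPERVISOR. Supervisor
notification is an append-only event log — the observable contract of
an email, without the infrastructure. Rejected samples stay queryable
but never enter the registration queue. Registration is an explicit
queue drain (review never blocks on it), idempotent, and mints: a
BioSample accession per sample, a BioSample accession per specimen
("specimen level sample"), an ENA accession per sample, and a ToLID per
specimen. The minters are labelled mocks — `SAMEA`/`ERS` plus
zero-padded counters, and ToLIDs as
`<prefix><Genus 3 letters><epithet 4 letters><n>` with `n` counting
specimens per species in order of first assignment — deterministic,
globally unique within a store, and explicitly not authoritative; real
registries plug in behind the same interfaces.

Every metadata change re-validates against the sample's **original**
schema version (updates must respect the SOP the sample was submitted
under), applies atomically or not at all, and writes one audit entry
per changed field with actor, timestamp, old and new value. The audit
table is append-only; the as-submitted metadata is retained so any
drift is provably explained by the audit chain. Image files associate
to specimens by filename (`SP123_1.png` → specimen SP123, index 1);
known specimen ids are matched longest-first because ids may themselves
contain underscores; unmatched files are reported, never fatal.

## Synthetic study material

The fixtures module is first-class code, not test scaffolding. The
taxonomy generator emits `n` species with syllable-table binomials
(ids from 9,000,000 up, so they cannot collide with real taxa),
`⌈synonym_fraction·n⌉` synonym rows, genus parents, and a
non-submittable flag on `⌈nonsubmittable_fraction·n⌉` species; defaults
0.25 and 0.1. The manifest generator emulates a GAL collection batch:
UK-range coordinates, 2020–2023 collection dates, vocabulary-valid
cells, barcode-conformant ids, and specimen structure controlled by
`specimen_sharing` (default 0.2 — a modest fraction of specimens yield
several tubes), `whole_organism_fraction` (default 0.25 of new
specimens) and `symbiont_fraction` (default 0). Shared specimens always
keep a consistent taxon and non-whole parts, so generated manifests
validate with zero errors by construction.

The injector plants requested rule violations into rows no other
injection touches and returns the exact (code, row, field) ground
truth, including both rows of a two-row conflict. Because a taxonomy
ERROR aborts later phases, mixing taxonomy-error codes with field/cross
codes in one manifest would mask the latter; the injector refuses such
requests, and the oracle experiment draws each manifest's codes from
one phase class (SYNONYM_CONVERTED, a warning, combines with either).
What the fixtures do **not** emulate: realistic geographic or temporal
collection distributions, real taxon names, spreadsheet-specific
artefacts (merged cells, formulae), or multi-manifest submission
histories — so passing tests demonstrate the rule logic, not robustness
to every artefact of real field data.

## Experiment sizes and numerical choices

The shipped experiments (also run by `scripts/acceptance.py`) use: 200
manifests × 20 rows with 1–5 injected violations for the validation
oracle; 100 manifests (5–25 rows) for graph invariants plus one random
edge drop/duplication each; 30 manifests for export projections; 500
random lifecycle operations; all on a 30-species taxonomy with synonym
fraction 0.3 and non-submittable fraction 0.15. These sizes exercise
every rule code and edge kind many times over while keeping the whole
run within seconds on one CPU. All randomness flows from a single seed
through a splitmix-style derivation (`seed·1000003 + salt mod 2^31`),
so every file and report is byte-reproducible. Ties and degenerate
inputs are handled explicitly: empty manifests are valid and produce
empty reports and empty-but-well-formed XML; an empty taxonomy resolves
everything to NOT_FOUND; manifest-level issues sort before row issues;
identifiers may not contain the "/" sample-key separator.

## Known limitations

No live archive, taxonomy or ToLID registry clients (the interfaces
are there; the implementations are pinned/mocked). No spreadsheet
data-validation dropdown generation. No lineage retrieval or
higher-rank population beyond the species fields. Resubmission of
corrected rejected samples is not modelled (they are held back,
queryable, terminal). The mock ToLID grammar does not claim to match
the production scheme.
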