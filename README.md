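# tolbroker

Sample-metadata brokering for biodiversity genome projects.

Large reference-genome programmes collect thousands of specimens through
Genome Acquisition Laboratories (GALs), each described by a tabular
*sample manifest*: who collected what organism, where and when, in which
rack/plate and tube/well, which part of the organism each tube holds.
Before any of it can be registered in a public archive it has to be
checked — taxonomically (species-level names that match the curated main
name of a submittable taxon), field by field (mandatory values,
controlled vocabularies, dates, coordinates) and across rows (one
specimen, one taxon; a whole organism can only occupy one tube; the
rack + tube pair that identifies a sample must be unique). `tolbroker`
implements that brokering core as a library and CLI:

* **Versioned manifest schemas** (`dtol-core` 2.4.0/2.4.1 bundled, plus
  a protist extension adding SALINITY, WATER_TEMPERATURE and PH) with
  controlled vocabularies, PUBLIC/INTERNAL visibility and term mappings
  onto Darwin Core, the ENA checklist vocabulary and MIxS.
* **Three-phase validation** producing a stable-coded issue report
  (14 rule codes, e.g. `SYNONYM_CONVERTED`, `DUPLICATE_WHOLE_ORGANISM`,
  `SPECIMEN_TAXON_CONFLICT`); taxonomy errors abort submission, warnings
  never block.
* **A specimen–sample relationship graph**: one specimen-level node per
  genetic individual, each sample joined by exactly one typed edge —
  *same as* (1:1, whole organisms), *sample derived from* (many:1,
  organism parts) or *sample symbiont of* (many:1).
* **Exporters**: ENA sample XML (`SAMPLE_SET`, checklist `ERC000053`,
  study `PRJEB40665`, relationship attributes), Darwin Core
  (`DATE_OF_COLLECTION → verbatimEventDate`,
  `DECIMAL_LATITUDE → decimalLatitude`,
  `TUBE_OR_WELL_ID → measurementID`, …), MIxS, and a full JSON view that
  always returns the manifest version a sample was submitted under.
* **A brokered lifecycle** over sqlite: submit (role-gated, notifies
  supervisors via an event log), accept/reject review, idempotent
  registration minting mock BioSample/ENA accessions and ToLIDs, an
  append-only audit trail for every metadata change, and specimen image
  association (`SP123_1.png`, `SP123_2.png`).
* **Synthetic fixtures**: seeded taxonomies (synonyms, ranks,
  submittability), clean manifests, and an error injector that returns
  machine-readable ground truth — the oracle the validator is measured
  against.

## Worked example

```sh
$ tolbroker fixtures taxonomy --n-species 20 --seed 7 --out tax.tsv
$ tolbroker fixtures manifest --n-rows 12 --taxonomy tax.tsv --seed 11 --out man.csv
$ tolbroker fixtures corrupt man.csv --taxonomy tax.tsv --rule VOCAB_VIOLATION --seed 8 --out bad.csv
$ tolbroker validate bad.csv --taxonomy tax.tsv
{
  "issues": [
    {
      "code": "VOCAB_VIOLATION",
      "field": "SEX",
      "message": "'f' is not an allowed term for SEX",
      "row_index": 4,
      "severity": "ERROR"
    }
  ],
  "passed": false,
  "phase_reached": "CROSS"
}
$ echo $?
1
```

The report says the manifest reached the cross-row phase (so taxonomy
passed), but row 4 used `f` where the SEX vocabulary requires one of
MALE/FEMALE/HERMAPHRODITE/UNKNOWN/NOT_COLLECTED; the non-zero exit
status is what gates submission. After fixing, the clean manifest flows
through the lifecycle:

```sh
$ tolbroker submit man.csv --taxonomy tax.tsv --store store.sqlite
$ tolbroker review --accept --store store.sqlite RK01100/TB0001
$ tolbroker register --store store.sqlite
{
  "RK01100/TB0001": {
    "biosample": "SAMEA00000002",
    "ena": "ERS0000001",
    "tolid": "xxCefxoce1"
  }
}
```

Registration minted a BioSample accession for the sample *and* its
specimen-level parent (`SAMEA00000001`), plus a mock ToLID built from
the species name; `tolbroker query SAMEA00000002 --store store.sqlite`
retrieves the record by accession together with the manifest version it
was submitted under.

Python API equivalents live in `tolbroker` (`load_schema`,
`read_manifest`, `run_validation`, `build_graph`, `to_ena_xml`,
`Broker`, …); see `docs/methods.md` for the model and its parameters.

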