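"""Validation engine: per-phase rules, gating, ordering, determinism."""

import pytest

from tolbroker import (Manifest, ManifestRecord, run_validation,
                       validate_cross_phase, validate_field_phase,
                       validate_taxonomy_phase)
from tolbroker.validate import RULE_CATALOGUE


def manifest_from(rows, version="2.4.1"):
    return Manifest(schema_version=version, records=[
        ManifestRecord(row_index=i + 1, values=dict(row))
        for i, row in enumerate(rows)
    ])


def row(taxonomy, **overrides):
    """A fully valid row against the session fixture taxonomy."""
    species = next(taxonomy.main(t) for t in taxonomy.taxon_ids()
                   if taxonomy.main(t).rank == "SPECIES"
                   and taxonomy.main(t).submittable)
    base = {
        "RACK_OR_PLATE_ID": "RK01", "TUBE_OR_WELL_ID": "TB01",
        "SPECIMEN_ID": "SP1", "SCIENTIFIC_NAME": species.name,
        "TAXON_ID": str(species.taxon_id), "ORGANISM_PART": "LEG",
        "SEX": "FEMALE", "DATE_OF_COLLECTION": "2021-05-04",
        "COLLECTION_LOCATION": "UK | Norfolk",
        "DECIMAL_LATITUDE": "52.2", "DECIMAL_LONGITUDE": "1.1",
        "GAL": "SANGER INSTITUTE",
    }
    base.update(overrides)
    return base


class TestTaxonomyPhase:
    def test_valid_rows_populate_and_pass(self, taxonomy):
        m = manifest_from([row(taxonomy, SCIENTIFIC_NAME="",
                               TUBE_OR_WELL_ID="TB01"),
                           row(taxonomy, TUBE_OR_WELL_ID="TB02",
                               SPECIMEN_ID="SP2")])
        reconciled, issues = validate_taxonomy_phase(m, taxonomy)
        assert issues == []
        assert reconciled.records[0].get("SCIENTIFIC_NAME")  # populated

    def test_synonym_row_converted_with_warning(self, taxonomy):
        syn = next(r for r in taxonomy.records if r.name_class == "SYNONYM"
                   and r.submittable)
        m = manifest_from([row(taxonomy, SCIENTIFIC_NAME=syn.name,
                               TAXON_ID=str(syn.taxon_id))])
        reconciled, issues = validate_taxonomy_phase(m, taxonomy)
        assert [i.code for i in issues] == ["SYNONYM_CONVERTED"]
        assert reconciled.records[0].get("SCIENTIFIC_NAME") == \
            taxonomy.main(syn.taxon_id).name

    def test_non_submittable_taxon_is_error(self, taxonomy):
        bad = next(taxonomy.main(t) for t in taxonomy.taxon_ids()
                   if taxonomy.main(t).rank == "SPECIES"
                   and not taxonomy.main(t).submittable)
        m = manifest_from([row(taxonomy, SCIENTIFIC_NAME=bad.name,
                               TAXON_ID=str(bad.taxon_id))])
        _, issues = validate_taxonomy_phase(m, taxonomy)
        assert [(i.code, i.severity) for i in issues] == \
            [("TAXON_NOT_SUBMITTABLE", "ERROR")]


class TestFieldPhase:
    def check(self, taxonomy, schema, **overrides):
        m = manifest_from([row(taxonomy, **overrides)])
        return validate_field_phase(m, schema)

    def test_compliant_row_is_clean(self, taxonomy, schema):
        assert self.check(taxonomy, schema) == []

    @pytest.mark.parametrize("overrides,code,severity", [
        ({"SEX": "Fem"}, "VOCAB_VIOLATION", "ERROR"),
        ({"SEX": ""}, "MISSING_MANDATORY", "ERROR"),
        ({"GAL": "NOT_PROVIDED"}, "MISSING_MANDATORY", "ERROR"),
        ({"DATE_OF_COLLECTION": "04/05/2021"}, "BAD_DATE", "ERROR"),
        ({"DATE_OF_COLLECTION": "2021-02-30"}, "BAD_DATE", "ERROR"),
        ({"DATE_OF_COLLECTION": "2021-05"}, "PARTIAL_DATE", "WARNING"),
        ({"DECIMAL_LATITUDE": "95.0"}, "BAD_COORDINATE", "ERROR"),
        ({"DECIMAL_LONGITUDE": "-190"}, "BAD_COORDINATE", "ERROR"),
        ({"DECIMAL_LATITUDE": "north"}, "BAD_COORDINATE", "ERROR"),
        ({"TUBE_OR_WELL_ID": "weird id!"}, "NONSTANDARD_TUBE_ID", "WARNING"),
    ])
    def test_single_cell_rules(self, taxonomy, schema, overrides, code,
                               severity):
        issues = self.check(taxonomy, schema, **overrides)
        assert [(i.code, i.severity) for i in issues] == [(code, severity)]
        assert issues[0].field == next(iter(overrides))

    def test_vocabulary_match_is_case_insensitive(self, taxonomy, schema):
        assert self.check(taxonomy, schema, SEX="female") == []

    def test_sentinel_allowed_where_vocabulary_lists_it(self, taxonomy,
                                                        schema):
        assert self.check(taxonomy, schema, SEX="NOT_COLLECTED") == []
        assert self.check(taxonomy, schema,
                          DATE_OF_COLLECTION="NOT_COLLECTED") == []


class TestCrossPhase:
    def pair(self, taxonomy, part_a="LEG", part_b="BLOOD", **b_overrides):
        a = row(taxonomy, ORGANISM_PART=part_a)
        b_overrides.setdefault("TUBE_OR_WELL_ID", "TB02")
        b = row(taxonomy, ORGANISM_PART=part_b, **b_overrides)
        return manifest_from([a, b])

    def test_whole_organism_cannot_recur(self, taxonomy):
        issues = validate_cross_phase(
            self.pair(taxonomy, part_a="WHOLE_ORGANISM"))
        assert {i.code for i in issues} == {"DUPLICATE_WHOLE_ORGANISM"}
        assert sorted(i.row_index for i in issues) == [1, 2]

    def test_one_specimen_two_taxa_conflicts(self, taxonomy):
        other = [taxonomy.main(t) for t in taxonomy.taxon_ids()
                 if taxonomy.main(t).rank == "SPECIES"][1]
        issues = validate_cross_phase(self.pair(
            taxonomy, SCIENTIFIC_NAME=other.name,
            TAXON_ID=str(other.taxon_id)))
        assert {(i.code, i.row_index) for i in issues} == {
            ("SPECIMEN_TAXON_CONFLICT", 1), ("SPECIMEN_TAXON_CONFLICT", 2)}

    def test_two_parts_one_specimen_is_fine(self, taxonomy):
        assert validate_cross_phase(self.pair(taxonomy)) == []

    def test_duplicate_rack_tube_pair(self, taxonomy):
        issues = validate_cross_phase(
            self.pair(taxonomy, SPECIMEN_ID="SP2", TUBE_OR_WELL_ID="TB01"))
        assert {i.code for i in issues} == {"DUPLICATE_SAMPLE_ID"}

    def test_registry_conflict_detected(self, taxonomy):
        class FakeRegistry:
            def registered_taxon(self, specimen_id):
                return 1234 if specimen_id == "SP1" else None

        issues = validate_cross_phase(self.pair(taxonomy), FakeRegistry())
        assert {i.code for i in issues} == {"SPECIMEN_TAXON_CONFLICT"}


class TestRunValidation:
    def test_taxonomy_failure_skips_later_phases(self, taxonomy, schema):
        m = manifest_from([
            row(taxonomy, SCIENTIFIC_NAME="Nullius nomen", TAXON_ID="",
                SEX="Fem")])  # SEX violation must NOT surface
        _, report = run_validation(m, schema, taxonomy)
        assert report.phase_reached == "TAXONOMY"
        assert report.codes() == {"TAXON_NOT_FOUND"}
        assert not report.passed

    def test_field_and_cross_phases_both_run(self, taxonomy, schema):
        a = row(taxonomy, SEX="Fem", ORGANISM_PART="WHOLE_ORGANISM")
        b = row(taxonomy, TUBE_OR_WELL_ID="TB02")
        _, report = run_validation(manifest_from([a, b]), schema, taxonomy)
        assert report.phase_reached == "CROSS"
        assert {"VOCAB_VIOLATION", "DUPLICATE_WHOLE_ORGANISM"} <= \
            report.codes()

    def test_warnings_never_block(self, taxonomy, schema):
        m = manifest_from([row(taxonomy, DATE_OF_COLLECTION="2021")])
        _, report = run_validation(m, schema, taxonomy)
        assert report.passed
        assert report.codes() == {"PARTIAL_DATE"}

    def test_issues_sorted_by_row_field_code(self, taxonomy, schema):
        a = row(taxonomy, SEX="Fem", DATE_OF_COLLECTION="bad")
        b = row(taxonomy, TUBE_OR_WELL_ID="TB02", DECIMAL_LATITUDE="99")
        _, report = run_validation(manifest_from([b, a][::-1]), schema,
                                   taxonomy)
        keys = [i.key() for i in report.issues]
        assert keys == sorted(keys)

    def test_identical_inputs_identical_serialised_reports(self, taxonomy,
                                                           schema,
                                                           clean_manifest):
        _, r1 = run_validation(clean_manifest, schema, taxonomy)
        _, r2 = run_validation(clean_manifest, schema, taxonomy)
        assert r1.to_json() == r2.to_json()

    def test_all_codes_belong_to_catalogue(self):
        assert len(RULE_CATALOGUE) == 14
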