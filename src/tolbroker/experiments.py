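"""Reproducible whole-pipeline experiments.

Each function here sets up synthetic study material with the fixtures
module, runs one slice of the pipeline end to end, and measures how it
behaved: does the validation engine recover exactly the violations that
were planted, do built graphs always satisfy the relationship
invariants, do the exports project precisely the public checklist, does
the lifecycle state machine hold up under random operation sequences.
The acceptance script and the top-level test suite both run these.
"""
from __future__ import annotations

import random
import tempfile
from pathlib import Path

from lxml import etree

from .broker import Broker, UserRole
from .errors import FixtureConfigError, InvalidTransition, UpdateRejected
from .exporters import ExportProfile, ena_xml_bytes
from .fixtures import (POST_TAXONOMY_CODES, generate_manifest,
                       generate_taxonomy, inject_errors)
from .graph import EDGE_TAGS, build_graph, check_graph
from .manifest import read_manifest
from .schemas import checklist_subset, load_schema
from .taxonomy import load_taxonomy
from .validate import TAXONOMY_ERROR_CODES, run_validation

_MOD = 2**31


def _derive_seed(seed: int, *salts: int) -> int:
    value = seed % _MOD
    for salt in salts:
        value = (value * 1_000_003 + salt) % _MOD
    return value


def _standard_material(workdir: Path, seed: int, n_species: int = 30):
    """A taxonomy snapshot plus its schema, shared by the experiments."""
    schema = load_schema("dtol-core", "2.4.1")
    tax_path = generate_taxonomy(
        n_species, synonym_fraction=0.3, nonsubmittable_fraction=0.15,
        seed=_derive_seed(seed, 1), out_path=workdir / "taxonomy.tsv")
    return schema, load_taxonomy(tax_path)


def validation_oracle_experiment(n_manifests: int = 200, n_rows: int = 20,
                                 seed: int = 0, workdir=None) -> dict:
    """Plant 1-5 violations per manifest and measure recovery.

    Rule codes are drawn across the whole catalogue, with
    taxonomy-ERROR codes and later-phase codes kept in separate
    manifests because a taxonomy failure legitimately aborts the later
    phases.  Precision and recall are computed over the multiset of
    (code, row, field) issues.
    """
    workdir = Path(workdir or tempfile.mkdtemp(prefix="tolbroker-oracle-"))
    schema, table = _standard_material(workdir, seed)
    taxonomy_pool = sorted(TAXONOMY_ERROR_CODES | {"SYNONYM_CONVERTED"})
    later_pool = sorted(POST_TAXONOMY_CODES | {"SYNONYM_CONVERTED"})
    tp = fp = fn = 0
    covered: set[str] = set()
    exact_matches = 0
    for i in range(1, n_manifests + 1):
        mseed = _derive_seed(seed, 2, i)
        clean = generate_manifest(
            n_rows, table, schema, specimen_sharing=0.2,
            whole_organism_fraction=0.25, seed=mseed,
            out_path=workdir / "clean.csv")
        rng = random.Random(_derive_seed(seed, 3, i))
        pool = taxonomy_pool if rng.random() < 0.4 else later_pool
        for _attempt in range(20):
            codes = [rng.choice(pool) for _ in range(rng.randint(1, 5))]
            rules = [(c, codes.count(c)) for c in sorted(set(codes))]
            try:
                corrupted, log = inject_errors(
                    clean, rules, table, schema,
                    seed=_derive_seed(seed, 4, i),
                    out_path=workdir / "corrupted.csv")
                break
            except FixtureConfigError:
                continue  # combination needs more rows than this manifest has
        else:
            raise FixtureConfigError("could not find an injectable rule set")
        covered.update(codes)
        manifest = read_manifest(corrupted, schema)
        _, report = run_validation(manifest, schema, table)
        detected = {}
        for issue in report.issues:
            detected[issue.key()] = detected.get(issue.key(), 0) + 1
        injected = {(r, f, c): n for (c, r, f), n in log.as_multiset().items()}
        for key in set(detected) | set(injected):
            d, j = detected.get(key, 0), injected.get(key, 0)
            tp += min(d, j)
            fp += max(d - j, 0)
            fn += max(j - d, 0)
        if detected == injected:
            exact_matches += 1
    return {
        "n_manifests": n_manifests,
        "n_rows": n_rows,
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
        "exact_match_fraction": exact_matches / n_manifests,
        "codes_covered": sorted(covered),
    }


def graph_invariant_experiment(n_manifests: int = 100, seed: int = 0,
                               workdir=None) -> dict:
    """Check relationship-graph invariants on valid manifests and that
    any single-edge mutation (drop or duplicate) is caught."""
    workdir = Path(workdir or tempfile.mkdtemp(prefix="tolbroker-graph-"))
    schema, table = _standard_material(workdir, seed)
    structurally_valid = 0
    mutations = mutations_caught = 0
    for i in range(1, n_manifests + 1):
        mseed = _derive_seed(seed, 5, i)
        rng = random.Random(mseed)
        path = generate_manifest(
            rng.randint(5, 25), table, schema,
            specimen_sharing=rng.uniform(0.0, 0.4),
            whole_organism_fraction=rng.uniform(0.0, 0.5),
            symbiont_fraction=rng.uniform(0.0, 0.3),
            seed=mseed, out_path=workdir / "graph.csv")
        manifest = read_manifest(path, schema)
        reconciled, report = run_validation(manifest, schema, table)
        assert report.passed, "fixture manifests must validate cleanly"
        graph = build_graph(reconciled)
        distinct = {r.get("SPECIMEN_ID") for r in reconciled.records}
        same_as = [e for e in graph.edges if e.kind == "SAME_AS"]
        ok = (
            not check_graph(graph)
            and len(graph.specimen_nodes()) == len(distinct)
            and len(graph.sample_nodes()) == len(reconciled.records)
            and all(e.child.organism_part == "WHOLE_ORGANISM"
                    for e in same_as)
            and len({id(e.parent) for e in same_as}) == len(same_as)
        )
        structurally_valid += ok
        if graph.edges:
            mutations += 1
            if rng.random() < 0.5:
                graph.edges.pop(rng.randrange(len(graph.edges)))
            else:
                graph.edges.append(graph.edges[rng.randrange(len(graph.edges))])
            mutations_caught += bool(check_graph(graph))
    return {
        "n_manifests": n_manifests,
        "valid_fraction": structurally_valid / n_manifests,
        "mutation_detection_rate":
            mutations_caught / mutations if mutations else 1.0,
    }


def export_projection_experiment(n_manifests: int = 30, seed: int = 0,
                                 workdir=None) -> dict:
    """Well-formedness of the archive XML, exactness of the public
    checklist projection, and the fixed Darwin Core term mappings."""
    from .exporters import to_darwin_core

    workdir = Path(workdir or tempfile.mkdtemp(prefix="tolbroker-export-"))
    schema, table = _standard_material(workdir, seed)
    public = {f.name for f in checklist_subset(schema)}
    relationship_tags = set(EDGE_TAGS.values())
    wellformed = projection_exact = dwc_ok = 0
    n_records = 0
    dwc_pairs = (("DATE_OF_COLLECTION", "verbatimEventDate"),
                 ("DECIMAL_LATITUDE", "decimalLatitude"),
                 ("TUBE_OR_WELL_ID", "measurementID"))
    for i in range(1, n_manifests + 1):
        mseed = _derive_seed(seed, 6, i)
        path = generate_manifest(
            random.Random(mseed).randint(3, 15), table, schema,
            symbiont_fraction=0.15, seed=mseed,
            out_path=workdir / "export.csv")
        manifest = read_manifest(path, schema)
        reconciled, report = run_validation(manifest, schema, table)
        assert report.passed
        graph = build_graph(reconciled)
        payload = ena_xml_bytes(graph, schema, ExportProfile(format="ena"))
        try:
            root = etree.fromstring(payload)
            wellformed += 1
        except etree.XMLSyntaxError:
            continue
        exact = True
        for sample in root.findall("SAMPLE"):
            tags = {t.text for t in sample.findall(".//TAG")}
            extras = tags - public - {"ENA-CHECKLIST"}
            if not (tags >= public and "ENA-CHECKLIST" in tags
                    and (extras == set() or (len(extras) == 1
                         and extras <= relationship_tags))):
                exact = False
        projection_exact += exact
        maps = to_darwin_core(reconciled.records, schema)
        ok = all(m.get(term) == r.get(field)
                 for r, m in zip(reconciled.records, maps)
                 for field, term in dwc_pairs)
        dwc_ok += ok
        n_records += len(reconciled.records)
    return {
        "n_manifests": n_manifests,
        "n_records": n_records,
        "xml_wellformed_fraction": wellformed / n_manifests,
        "checklist_projection_exact_fraction": projection_exact / n_manifests,
        "dwc_mapping_fraction": dwc_ok / n_manifests,
    }


def lifecycle_experiment(n_ops: int = 500, seed: int = 0,
                         workdir=None) -> dict:
    """Hammer the lifecycle state machine with random operations and
    verify accession counting, audit completeness and version recall."""
    workdir = Path(workdir or tempfile.mkdtemp(prefix="tolbroker-life-"))
    schema, table = _standard_material(workdir, seed)
    rng = random.Random(_derive_seed(seed, 7))
    submitter = UserRole("alice", "SAMPLE_SUBMITTER")
    supervisor = UserRole("bob", "SAMPLE_SUPERVISOR")
    broker = Broker()
    state_violations = 0
    manifest_counter = 0

    def submit_new():
        nonlocal manifest_counter
        manifest_counter += 1
        path = generate_manifest(
            rng.randint(2, 8), table, schema,
            seed=_derive_seed(seed, 8, manifest_counter),
            out_path=workdir / "life.csv")
        manifest = read_manifest(path, schema)
        reconciled, report = run_validation(manifest, schema, table, broker)
        if report.passed:
            broker.submit_manifest(reconciled, report, submitter)

    submit_new()
    for _ in range(n_ops):
        op = rng.choice(["submit", "accept", "reject", "register",
                         "update", "query"])
        try:
            if op == "submit":
                submit_new()
            elif op in ("accept", "reject"):
                pool = broker.records()
                if pool:
                    keys = [rng.choice(pool).sample_key]
                    broker.review(keys, op.upper(), supervisor)
            elif op == "register":
                broker.register_accepted()
            elif op == "update":
                pool = broker.records()
                if pool:
                    broker.update_sample(
                        rng.choice(pool).sample_key,
                        {"COLLECTED_BY": f"Curator {rng.randint(1, 9)}"},
                        supervisor)
            elif op == "query":
                pool = broker.records()
                if pool:
                    broker.query_sample(rng.choice(pool).sample_key)
        except (InvalidTransition, UpdateRejected):
            pass  # refusing an illegal transition is correct behaviour
        for rec in broker.records():
            has_acc = rec.biosample_accession is not None
            if (rec.state == "SUBMITTED") != has_acc:
                state_violations += 1

    # Accession arithmetic: one specimen with two samples -> 3 BioSamples.
    counting = Broker()
    path = generate_manifest(3, table, schema, specimen_sharing=0.0,
                             whole_organism_fraction=0.0,
                             seed=_derive_seed(seed, 9),
                             out_path=workdir / "count.csv")
    manifest = read_manifest(path, schema)
    for rec in manifest.records[1:]:
        rec.values["SPECIMEN_ID"] = manifest.records[0].get("SPECIMEN_ID")
        rec.values["SCIENTIFIC_NAME"] = manifest.records[0].get("SCIENTIFIC_NAME")
        rec.values["TAXON_ID"] = manifest.records[0].get("TAXON_ID")
    manifest.records = manifest.records[:2]
    reconciled, report = run_validation(manifest, schema, table)
    assert report.passed
    created = counting.submit_manifest(reconciled, report, submitter)
    counting.review([r.sample_key for r in created], "ACCEPT", supervisor)
    registered = counting.register_accepted()
    accessions = {r.biosample_accession for r in registered}
    sp_row = counting.db.execute(
        "SELECT biosample_accession FROM specimens").fetchall()
    accessions.update(a for (a,) in sp_row if a)

    # Audit completeness on the hammered store: every difference between
    # current and as-submitted metadata must be explained by audit entries.
    unexplained = 0
    for rec in broker.records():
        submitted = broker.submitted_metadata(rec.sample_key)
        audited = {e.field for e in broker.audit_trail(rec.sample_key)}
        for field_name, value in rec.metadata.items():
            if submitted.get(field_name) != value and field_name not in audited:
                unexplained += 1
    version_recalled = all(
        broker.query_sample(r.sample_key).schema_version == schema.version
        for r in broker.records())
    return {
        "n_ops": n_ops,
        "state_violations": state_violations,
        "accessions_for_two_sample_specimen": len(accessions),
        "unexplained_metadata_changes": unexplained,
        "schema_version_recalled": float(version_recalled),
        "n_samples_in_store": len(broker.records()),
    }


def determinism_experiment(seed: int = 0, workdir=None) -> dict:
    """Byte-identical regeneration under a repeated seed."""
    workdir = Path(workdir or tempfile.mkdtemp(prefix="tolbroker-det-"))
    schema = load_schema("dtol-core", "2.4.1")
    pairs = []
    for which in ("a", "b"):
        tax = generate_taxonomy(25, 0.25, 0.1, seed=_derive_seed(seed, 10),
                                out_path=workdir / f"tax-{which}.tsv")
        man = generate_manifest(
            15, load_taxonomy(tax), schema, seed=_derive_seed(seed, 11),
            out_path=workdir / f"man-{which}.csv")
        corrupted, log = inject_errors(
            man, [("VOCAB_VIOLATION", 1), ("BAD_DATE", 1)],
            load_taxonomy(tax), schema, seed=_derive_seed(seed, 12),
            out_path=workdir / f"bad-{which}.csv")
        pairs.append((tax.read_bytes(), Path(man).read_bytes(),
                      corrupted.read_bytes(), log.to_json()))
    identical = pairs[0] == pairs[1]
    return {"byte_identical": float(identical)}
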