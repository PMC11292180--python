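import pytest

from tolbroker import (generate_manifest, generate_taxonomy, load_schema,
                       load_taxonomy, read_manifest)


@pytest.fixture(scope="session")
def schema():
    return load_schema("dtol-core", "2.4.1")


@pytest.fixture(scope="session")
def taxonomy_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("taxonomy") / "taxonomy.tsv"
    return generate_taxonomy(20, synonym_fraction=0.25,
                             nonsubmittable_fraction=0.1, seed=7,
                             out_path=path)


@pytest.fixture(scope="session")
def taxonomy(taxonomy_path):
    return load_taxonomy(taxonomy_path)


@pytest.fixture(scope="session")
def clean_manifest_path(tmp_path_factory, taxonomy, schema):
    path = tmp_path_factory.mktemp("manifests") / "clean.csv"
    return generate_manifest(12, taxonomy, schema, specimen_sharing=0.25,
                             whole_organism_fraction=0.25, seed=11,
                             out_path=path)


@pytest.fixture
def clean_manifest(clean_manifest_path, schema):
    return read_manifest(clean_manifest_path, schema)
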