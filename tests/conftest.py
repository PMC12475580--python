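import warnings

import pytest

from conservemap.fixtures import FamilySpec, generate_family

# idealised fixture geometry intentionally trips "missing backbone" style
# warnings in some negative-path tests; keep the suite output clean
warnings.filterwarnings("ignore", category=UserWarning, module="conservemap")

SPECIES_PLAN = (
    ("Homo sapiens", 92.0, 1.0),
    ("Mus musculus", 85.0, 1.0),
    ("Danio rerio", 78.0, 1.0),
    ("Xenopus laevis", 72.0, 1.0),
    ("Drosophila melanogaster", 64.0, 1.0),
)


@pytest.fixture(scope="session")
def family():
    """A reproducible 5-species ortholog family with decoys and truth table."""
    spec = FamilySpec(
        query_length=120,
        species_plan=SPECIES_PLAN,
        decoys_per_species=2,
        seed=11,
    )
    return generate_family(spec)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """A fixture tree on disk: db_root, query FASTA, struct-db and PDB files."""
    from conservemap.fixtures import write_fixture_set

    out = tmp_path_factory.mktemp("fixture_set")
    return write_fixture_set(out, seed=3)
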