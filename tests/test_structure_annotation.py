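"""Secondary-structure assignment, query mapping and the recursive search."""

import numpy as np
import pytest

from conservemap.fixtures import (
    build_backbone,
    generate_ideal_structure,
    write_chain_pdb,
    STRAND_PHI,
    STRAND_PSI,
)
from conservemap.ortholog_search import FilterSettings
from conservemap.species_db import ProteinSequence
from conservemap.structure_annotation import (
    Residue,
    SSString,
    StructureChain,
    StructureMatch,
    StructureSeqRecord,
    StructureSequenceDatabase,
    assign_secondary_structure,
    map_structure_to_query,
    read_structure_chain,
    recursive_structure_search,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _reference_dssp(path):
    """Independent oracle: mdtraj's DSSP, collapsed with the same 3-state rule."""
    import mdtraj as md

    raw = "".join(md.compute_dssp(md.load(str(path)), simplified=False)[0])
    return "".join(c if c in "HE" else "-" for c in raw)


@pytest.fixture(scope="module")
def fixture_suite(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("ss")
    paths = {}
    for kind, length in (
        ("helix", 15), ("helix", 24), ("helix", 40),
        ("hairpin", 16), ("hairpin", 20), ("hairpin", 30),
    ):
        chain = generate_ideal_structure(kind, length)
        path = tmp / f"{chain.structure_id}.pdb"
        write_chain_pdb(chain, path)
        paths[(kind, length)] = path
    return paths


def test_ideal_helix_mostly_helical(fixture_suite):
    chain = read_structure_chain(fixture_suite[("helix", 15)])
    states = assign_secondary_structure(chain)
    assert states.count("H") >= 11


def test_ideal_hairpin_strand_cores(fixture_suite):
    chain = read_structure_chain(fixture_suite[("hairpin", 20)])
    states = assign_secondary_structure(chain)
    s_len = (20 - 4) // 2
    # interior strand residues (away from termini and turn) must be E
    assert set(states[2 : s_len - 1]) == {"E"}
    assert set(states[-(s_len - 1) : -2]) == {"E"}


def test_agreement_with_reference_dssp(fixture_suite):
    total = agree = 0
    for path in fixture_suite.values():
        chain = read_structure_chain(path)
        mine = assign_secondary_structure(chain)
        ref = _reference_dssp(path)
        assert len(mine) == len(ref)
        total += len(ref)
        agree += sum(a == b for a, b in zip(mine, ref))
    assert agree / total >= 0.95


def test_isolated_extended_strand_is_coil():
    backbone = build_backbone([(STRAND_PHI, STRAND_PSI)] * 12)
    chain = StructureChain(
        structure_id="EXT",
        chain_id="A",
        residues=tuple(
            Residue(seq_index=i + 1, amino_acid="A", backbone=atoms)
            for i, atoms in enumerate(backbone)
        ),
    )
    assert assign_secondary_structure(chain) == "-" * 12


def test_missing_backbone_atoms_forced_coil():
    chain = generate_ideal_structure("helix", 15)
    residues = list(chain.residues)
    gutted = dict(residues[7].backbone)
    gutted.pop("O")
    residues[7] = Residue(seq_index=residues[7].seq_index, amino_acid="A", backbone=gutted)
    broken = StructureChain(structure_id="HLX", chain_id="A", residues=tuple(residues))
    with pytest.warns(UserWarning, match="missing backbone"):
        states = assign_secondary_structure(broken)
    assert states[7] == "-"


def test_too_few_complete_residues_rejected():
    chain = generate_ideal_structure("helix", 15)
    short = StructureChain(
        structure_id="TINY", chain_id="A", residues=chain.residues[:4]
    )
    with pytest.raises(ValueError):
        assign_secondary_structure(short)


def _query_of(seq):
    return ProteinSequence(id="q", description="", residues=seq)


def test_map_covers_interval_and_pads_x():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list(AA), 100))
    chain = generate_ideal_structure("helix", 50, seq[:50])
    match = StructureMatch(chain=chain, query_interval=(1, 50), identity_pct=100.0)
    ss = map_structure_to_query(match, _query_of(seq))
    assert len(ss.states) == 100
    assert set(ss.states[50:]) == {"X"}
    assert set(ss.states[:50]) <= set("AB-")


def test_unmodelled_internal_residues_map_to_x():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list(AA), 40))
    chain = generate_ideal_structure("helix", 40, seq)
    # drop three residues from the coordinates: an internal disordered gap
    residues = chain.residues[:20] + chain.residues[23:]
    gapped = StructureChain(
        structure_id=chain.structure_id, chain_id="A", residues=residues
    )
    match = StructureMatch(chain=gapped, query_interval=(1, 40), identity_pct=100.0)
    ss = map_structure_to_query(match, _query_of(seq))
    assert len(ss.states) == 40
    assert ss.states[20:23] == "XXX"
    assert "X" not in ss.states[:20]


def test_mapped_length_always_equals_query_length():
    rng = np.random.default_rng(4)
    for qlen, clen in ((60, 30), (30, 30), (35, 50)):
        seq = "".join(rng.choice(list(AA), qlen))
        chain = generate_ideal_structure("helix", clen, seq[: min(qlen, clen)].ljust(clen, "A"))
        match = StructureMatch(
            chain=chain, query_interval=(1, min(qlen, clen)), identity_pct=100.0
        )
        ss = map_structure_to_query(match, _query_of(seq))
        assert len(ss.states) == qlen


def test_ssstring_invariants_enforced():
    with pytest.raises(ValueError):
        SSString(states="AAXZ", source_label="s", covered_interval=(1, 4))
    with pytest.raises(ValueError):
        SSString(states="AAAA", source_label="s", covered_interval=(1, 3))
    with pytest.raises(ValueError):
        SSString(states="AAAA", source_label="s", covered_interval=(2, 5))


def _struct_setup(tmp_path, query_seq, pieces):
    """Write PDBs + struct-db FASTA for (structure_id, qstart, qend) pieces."""
    records = []
    for sid, lo, hi in pieces:
        seq = query_seq[lo - 1 : hi]
        chain = generate_ideal_structure("helix", hi - lo + 1, seq)
        chain = StructureChain(
            structure_id=sid, chain_id="A", residues=chain.residues
        )
        write_chain_pdb(chain, tmp_path / f"{sid}.pdb")
        records.append(StructureSeqRecord(structure_id=sid, chain_id="A", sequence=seq))
    db = StructureSequenceDatabase(records)
    from conservemap.structure_annotation import directory_chain_loader

    return db, directory_chain_loader(tmp_path)


def test_two_domain_query_yields_two_structures_linker_x(tmp_path):
    rng = np.random.default_rng(6)
    seq = "".join(rng.choice(list(AA), 130))
    # domain A: 1-50, linker 51-80, domain B: 81-130
    db, loader = _struct_setup(tmp_path, seq, [("DOMA", 1, 50), ("DOMB", 81, 130)])
    out = recursive_structure_search(
        _query_of(seq), db, FilterSettings(50.0, 100.0, 20.0), loader
    )
    assert len(out) == 2
    labels = {ss.source_label for ss in out}
    assert labels == {"DOMA", "DOMB"}
    for ss in out:
        assert ss.states[50:80] == "X" * 30  # linker never modelled


def test_nineteen_residue_tail_triggers_no_second_search(tmp_path):
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list(AA), 119))
    db, loader = _struct_setup(
        tmp_path, seq, [("CORE", 1, 100), ("TAIL", 101, 119)]
    )
    out = recursive_structure_search(
        _query_of(seq), db, FilterSettings(50.0, 100.0, 20.0), loader
    )
    assert [ss.source_label for ss in out] == ["CORE"]


def test_twenty_residue_tail_triggers_second_search(tmp_path):
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list(AA), 120))
    db, loader = _struct_setup(
        tmp_path, seq, [("CORE", 1, 100), ("TAIL", 101, 120)]
    )
    out = recursive_structure_search(
        _query_of(seq), db, FilterSettings(50.0, 100.0, 20.0), loader
    )
    assert [ss.source_label for ss in out] == ["CORE", "TAIL"]


def test_fully_covered_query_runs_once(tmp_path):
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list(AA), 60))
    db, loader = _struct_setup(tmp_path, seq, [("FULL", 1, 60)])
    out = recursive_structure_search(
        _query_of(seq), db, FilterSettings(50.0, 100.0, 20.0), loader
    )
    assert len(out) == 1
    assert out[0].covered_interval == (1, 60)


def test_no_match_returns_empty_with_notice(tmp_path):
    rng = np.random.default_rng(10)
    seq = "".join(rng.choice(list(AA), 60))
    unrelated = "".join(rng.choice(list(AA), 60))
    db, loader = _struct_setup(tmp_path, unrelated, [("NOPE", 1, 60)])
    with pytest.warns(UserWarning, match="no structure match"):
        out = recursive_structure_search(
            _query_of(seq), db, FilterSettings(50.0, 100.0, 20.0), loader
        )
    assert out == []


def test_pdb_roundtrip_coordinates(tmp_path):
    chain = generate_ideal_structure("hairpin", 20)
    path = tmp_path / "h.pdb"
    write_chain_pdb(chain, path)
    back = read_structure_chain(path)
    assert len(back.residues) == 20
    for orig, rt in zip(chain.residues, back.residues):
        for atom, pos in orig.backbone.items():
            assert np.allclose(rt.backbone[atom], pos, atol=1.5e-3)
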