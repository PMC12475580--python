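"""Search and filter semantics, checked against independent alignment oracles."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from conservemap.ortholog_search import (
    FilterSettings,
    SearchHit,
    compute_identity_pct,
    filter_hits,
    search_database,
)
from conservemap.pairwise import (
    GAP_EXTEND,
    GAP_OPEN,
    PairwiseAlignment,
    needleman_wunsch,
    smith_waterman,
)
from conservemap.species_db import ProteinSequence, SpeciesDatabase

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM = substitution_matrices.load("BLOSUM62")


def _oracle(mode="local"):
    aligner = Align.PairwiseAligner(
        mode=mode, open_gap_score=-(GAP_OPEN + GAP_EXTEND), extend_gap_score=-GAP_EXTEND
    )
    aligner.substitution_matrix = BLOSUM
    return aligner


def _rescore(aln: PairwiseAlignment) -> int:
    """Independent re-scorer: walk the traceback strings and sum scores."""
    total, in_gap = 0, False
    for a, b in zip(aln.aligned_a, aln.aligned_b):
        if a == "-" or b == "-":
            total -= GAP_EXTEND + (GAP_OPEN if not in_gap else 0)
            in_gap = True
        else:
            total += int(BLOSUM[a][b])
            in_gap = False
    return total


def test_local_and_global_scores_match_reference_aligner():
    rng = np.random.default_rng(42)
    local, glob = _oracle("local"), _oracle("global")
    for _ in range(60):
        a = "".join(rng.choice(list(AA), rng.integers(5, 60)))
        b = "".join(rng.choice(list(AA), rng.integers(5, 60)))
        mine = smith_waterman(a, b)
        assert mine.score == local.score(a, b)
        assert mine.score == _rescore(mine)
        gmine = needleman_wunsch(a, b)
        assert gmine.score == glob.score(a, b)


def test_identity_is_recomputable_from_traceback():
    rng = np.random.default_rng(7)
    for _ in range(20):
        a = "".join(rng.choice(list(AA), 50))
        b = "".join(rng.choice(list(AA), 50))
        aln = smith_waterman(a, b)
        if aln.columns == 0:
            continue
        naive = sum(
            1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-"
        )
        assert compute_identity_pct(aln) == pytest.approx(100.0 * naive / aln.columns)


def test_identity_simple_cases():
    self_aln = smith_waterman("ACDEFGHIKL", "ACDEFGHIKL")
    assert compute_identity_pct(self_aln) == 100.0
    # 10 columns, 5 identities, 1 gap column
    crafted = PairwiseAlignment(
        score=0, aligned_a="ACDEF-WYKL", aligned_b="ACDEFGWACD",
        a_start=0, a_end=9, b_start=0, b_end=10,
    )
    assert compute_identity_pct(crafted) == pytest.approx(
        100.0 * crafted.identities / 10
    )
    assert crafted.identities == 6  # A C D E F W identical
    with pytest.raises(ValueError):
        compute_identity_pct(
            PairwiseAlignment(0, "", "", 0, 0, 0, 0)
        )


def _db(name, seqs):
    return SpeciesDatabase(
        species_name=name,
        taxonomy_path=("T",),
        sequences=tuple(
            ProteinSequence(id=f"{name}_{i}", description="", residues=s)
            for i, s in enumerate(seqs)
        ),
    )


def test_self_match_wins_with_full_identity():
    rng = np.random.default_rng(0)
    query_seq = "".join(rng.choice(list(AA), 80))
    decoys = ["".join(rng.choice(list(AA), 80)) for _ in range(3)]
    db = _db("Sp", [decoys[0], query_seq, *decoys[1:]])
    query = ProteinSequence(id="q", description="", residues=query_seq)
    hit = search_database(query, db)
    assert hit.hit.residues == query_seq
    assert hit.identity_pct == 100.0
    assert hit.length_ratio_pct == 100.0


def test_top_hit_matches_exhaustive_smith_waterman():
    rng = np.random.default_rng(1)
    query = ProteinSequence(
        id="q", description="", residues="".join(rng.choice(list(AA), 30))
    )
    peptides = ["".join(rng.choice(list(AA), rng.integers(8, 20))) for _ in range(5)]
    db = _db("Sp", peptides)
    hit = search_database(query, db)
    oracle = _oracle("local")
    scores = [oracle.score(query.residues, p) for p in peptides]
    best = max(
        range(5), key=lambda i: (scores[i], -ord(db.sequences[i].id[-1]))
    )
    assert hit.score == scores[best]


def test_ortholog_beats_decoy_paralog(family):
    query, registry, truth = family
    for db in registry.databases:
        hit = search_database(query, db)
        assert hit.hit.id.endswith("_ORTH"), f"{db.species_name} picked a decoy"
        # search identity tracks the planted substitution identity
        assert hit.identity_pct == pytest.approx(truth[db.species_name], abs=6.0)


def test_empty_database_returns_none():
    db = _db("Sp", ["ACDEF"])
    object.__setattr__(db, "sequences", ())
    query = ProteinSequence(id="q", description="", residues="ACDEF")
    with pytest.warns(UserWarning):
        assert search_database(query, db) is None


def _hit(identity, length_ratio, species="Sp", hid="h"):
    return SearchHit(
        species_name=species,
        hit=ProteinSequence(id=hid, description="", residues="ACDEF"),
        score=10,
        identity_pct=identity,
        length_ratio_pct=length_ratio,
        alignment=PairwiseAlignment(10, "ACDEF", "ACDEF", 0, 5, 0, 5),
    )


def test_length_window_worked_example():
    """Threshold 20% on a 100-residue query keeps lengths 80-120 inclusive."""
    settings_ = FilterSettings(0.0, 100.0, 20.0)
    hits = [_hit(60.0, ratio, hid=f"h{ratio}") for ratio in (79.0, 80.0, 120.0, 121.0)]
    kept = {h.length_ratio_pct for h in filter_hits(hits, settings_, 100)}
    assert kept == {80.0, 120.0}


def test_identity_window_inclusive_on_keep_side():
    settings_ = FilterSettings(50.0, 90.0, 100.0)
    hits = [_hit(ident, 100.0, hid=f"h{ident}") for ident in (49.9, 50.0, 90.0, 90.1)]
    kept = {h.identity_pct for h in filter_hits(hits, settings_, 100)}
    assert kept == {50.0, 90.0}


def test_wide_open_filter_keeps_everything_in_order():
    hits = [_hit(10.0 * i, 50.0 + 10.0 * i, hid=f"h{i}") for i in range(1, 8)]
    kept = filter_hits(hits, FilterSettings(0.0, 100.0, 100.0), 100)
    assert kept == hits


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0, max_value=100),
            st.floats(min_value=1, max_value=200),
        ),
        max_size=20,
    ),
    st.floats(min_value=0, max_value=100),
    st.floats(min_value=0, max_value=100),
)
def test_raising_lower_identity_shrinks_kept_set(hit_params, lo1, lo2):
    lo_small, lo_big = sorted((lo1, lo2))
    hits = [
        _hit(ident, ratio, hid=f"h{i}")
        for i, (ident, ratio) in enumerate(hit_params)
    ]
    kept_loose = filter_hits(hits, FilterSettings(lo_small, 100.0, 50.0), 100)
    kept_tight = filter_hits(hits, FilterSettings(lo_big, 100.0, 50.0), 100)
    assert set(h.hit.id for h in kept_tight) <= set(h.hit.id for h in kept_loose)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0, max_value=100),
            st.floats(min_value=1, max_value=200),
        ),
        max_size=20,
    ),
    st.floats(min_value=0, max_value=100),
    st.floats(min_value=0, max_value=100),
)
def test_widening_length_threshold_grows_kept_set(hit_params, t1, t2):
    t_small, t_big = sorted((t1, t2))
    hits = [
        _hit(ident, ratio, hid=f"h{i}")
        for i, (ident, ratio) in enumerate(hit_params)
    ]
    kept_narrow = filter_hits(hits, FilterSettings(0.0, 100.0, t_small), 100)
    kept_wide = filter_hits(hits, FilterSettings(0.0, 100.0, t_big), 100)
    assert set(h.hit.id for h in kept_narrow) <= set(h.hit.id for h in kept_wide)


def test_filter_settings_validation():
    with pytest.raises(ValueError):
        FilterSettings(60.0, 50.0, 20.0)
    with pytest.raises(ValueError):
        FilterSettings(-1.0, 50.0, 20.0)
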