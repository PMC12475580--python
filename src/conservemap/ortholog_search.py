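"""Best-hit-per-species database search and identity/length filtering.

The search contract mirrors protein BLAST: for each species database the
single sequence with the highest gapped local-alignment score against the
query is returned (its most likely functional ortholog), then hits are kept
only if their percent identity falls inside a user window and their length
falls inside a symmetric window around the query length. Taking one hit per
species suppresses paralogs and redundant entries at the cost of missing
duplicated same-function genes.

Search acceleration uses exact 3-mer seeding with a two-hit diagonal filter;
candidate subjects are then scored with exact Smith-Waterman, so seeding
decides *which* subjects are scored, never the score itself. Small problems
(fewer than 4096 matrix cells, or either sequence under 40 residues) skip
seeding entirely: full dynamic programming is as fast there.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .pairwise import PairwiseAlignment, identity_pct, smith_waterman
from .species_db import ProteinSequence, SpeciesDatabase

SEED_K = 3
#: Two seeds on one diagonal within this span make a subject a candidate.
TWO_HIT_SPAN = 64
#: Below this many DP cells, exhaustive alignment beats seeding overhead.
SMALL_PROBLEM_CELLS = 4096
#: Sequences shorter than this always take the exhaustive path.
SHORT_SEQ_LEN = 40


@dataclass(frozen=True)
class SearchHit:
    """The best local alignment of the query against one species database."""

    species_name: str
    hit: ProteinSequence
    score: int
    identity_pct: float
    length_ratio_pct: float
    alignment: PairwiseAlignment

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct must be in [0, 100]")
        if self.length_ratio_pct <= 0:
            raise ValueError("length_ratio_pct must be positive")


@dataclass(frozen=True)
class FilterSettings:
    """Identity window and symmetric length window, all in percent.

    ``lower_identity_pct`` defaults to 50 and ``length_threshold_pct`` to 20,
    useful starting points for compact globular proteins; both usually need
    per-protein tuning. Bounds are inclusive on the keep side.
    """

    lower_identity_pct: float = 50.0
    upper_identity_pct: float = 100.0
    length_threshold_pct: float = 20.0

    def __post_init__(self) -> None:
        for name in ("lower_identity_pct", "upper_identity_pct", "length_threshold_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.lower_identity_pct > self.upper_identity_pct:
            raise ValueError("lower_identity_pct must not exceed upper_identity_pct")


def compute_identity_pct(aln: PairwiseAlignment) -> float:
    """Percent identity: identical pairs over all alignment columns, gaps included."""
    return identity_pct(aln)


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _passes_two_hit(query_index: dict[str, list[int]], subject: str) -> bool:
    """True when two non-overlapping 3-mer seeds share a diagonal within span."""
    last_on_diag: dict[int, int] = {}
    for j in range(len(subject) - SEED_K + 1):
        kmer = subject[j : j + SEED_K]
        for i in query_index.get(kmer, ()):
            diag = j - i
            prev = last_on_diag.get(diag)
            if prev is not None and SEED_K <= j - prev <= TWO_HIT_SPAN:
                return True
            if prev is None or j - prev >= SEED_K:
                last_on_diag[diag] = j
    return False


def _candidate_ids(query: str, db: SpeciesDatabase) -> list[int]:
    index = _kmer_positions(query, SEED_K)
    out = []
    for i, rec in enumerate(db.sequences):
        subj = rec.residues
        if (
            len(query) * len(subj) <= SMALL_PROBLEM_CELLS
            or min(len(query), len(subj)) < SHORT_SEQ_LEN
            or _passes_two_hit(index, subj)
        ):
            out.append(i)
    return out


def search_database(
    query: ProteinSequence, db: SpeciesDatabase
) -> SearchHit | None:
    """Return the database sequence with the maximal local-alignment score.

    Ties are broken lexicographically by sequence id. Returns ``None`` (with a
    warning) only for an empty database. When the seeding prefilter rejects
    every subject the whole database is scored exhaustively so the maximal-
    score postcondition still holds for unrelated sequence sets.
    """
    if not query.residues:
        raise ValueError("query must be non-empty")
    if not db.sequences:
        warnings.warn(f"empty database for {db.species_name}", stacklevel=2)
        return None

    candidates = _candidate_ids(query.residues, db)
    if not candidates:
        candidates = list(range(len(db.sequences)))

    best: tuple[int, str] | None = None
    best_rec: ProteinSequence | None = None
    best_aln: PairwiseAlignment | None = None
    for i in candidates:
        rec = db.sequences[i]
        aln = smith_waterman(query.residues, rec.residues)
        key = (-aln.score, rec.id)
        if best is None or key < best:
            best = key
            best_rec = rec
            best_aln = aln
    assert best_rec is not None and best_aln is not None
    return SearchHit(
        species_name=db.species_name,
        hit=best_rec,
        score=best_aln.score,
        identity_pct=compute_identity_pct(best_aln),
        length_ratio_pct=100.0 * len(best_rec) / len(query),
        alignment=best_aln,
    )


def search_registry(query: ProteinSequence, registry) -> list[SearchHit]:
    """One best hit per active species, in registry order; empty dbs skipped."""
    hits = []
    for db in registry.active():
        hit = search_database(query, db)
        if hit is not None:
            hits.append(hit)
    return hits


def filter_hits(
    hits: Sequence[SearchHit], settings: FilterSettings, query_len: int
) -> list[SearchHit]:
    """Keep hits inside the identity window and the symmetric length window.

    A hit is kept iff ``lower <= identity_pct <= upper`` and its length ratio
    lies in ``[100 - t, 100 + t]`` percent of the query length (e.g. t = 20
    keeps lengths between 80% and 120% of the query). Order is preserved.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    lo_len = 100.0 - settings.length_threshold_pct
    hi_len = 100.0 + settings.length_threshold_pct
    return [
        h
        for h in hits
        if settings.lower_identity_pct <= h.identity_pct <= settings.upper_identity_pct
        and lo_len <= h.length_ratio_pct <= hi_len
    ]
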