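"""Secondary-structure assignment from coordinates and mapping onto a query.

Assignment implements the Kabsch-Sander hydrogen-bond core: the amide H is
rebuilt from the preceding peptide plane (N-H antiparallel to the previous
C=O), a hydrogen bond is declared when the electrostatic energy

    E = 27.888 * (1/r(ON) + 1/r(CH) - 1/r(OH) - 1/r(CN))   [kcal/mol]

falls below -0.5, helices are runs of consecutive i -> i+4 bonded turns, and
strands are residues in parallel/antiparallel bridge ladders. The eight-state
vocabulary is collapsed to three: only 4-helices map to helix and only ladder
strands to strand; 3-10/pi helices, isolated bridges, turns and bends are
reported as unstructured -- the conservative reading when only "alpha helix"
and "beta strand" are displayed.

Query annotation uses the four-letter convention: ``A`` alpha helix, ``B``
beta strand, ``-`` unstructured, ``X`` not modelled (or outside the interval
covered by the matched structure). When the best structure match leaves query
segments of 20 or more residues uncovered, those segments are re-searched
iteratively so multi-domain proteins pick up one structure per domain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import gemmi
import numpy as np

from .ortholog_search import FilterSettings
from .pairwise import needleman_wunsch, identity_pct, smith_waterman
from .species_db import ProteinSequence

#: Minimum uncovered segment length that triggers a further structure search.
RECURSION_MIN_SEGMENT = 20

HBOND_ENERGY_CUTOFF = -0.5
HBOND_FACTOR = 27.888  # 0.084 e^2 * 332 in kcal/mol*Angstrom
PEPTIDE_BOND_MAX = 2.5  # C(i-1)-N(i) distance beyond which the chain breaks

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Residue:
    seq_index: int  # author numbering, strictly increasing within a chain
    amino_acid: str
    backbone: dict[str, np.ndarray]  # subset of N/CA/C/O -> xyz in Angstrom

    @property
    def complete(self) -> bool:
        return all(a in self.backbone for a in BACKBONE_ATOMS)


@dataclass(frozen=True)
class StructureChain:
    """Ordered backbone residues of one chain of one coordinate file."""

    structure_id: str
    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("chain has no residues")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("seq_index must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)


@dataclass(frozen=True)
class StructureMatch:
    """A chain matched to a query interval (1-based inclusive)."""

    chain: StructureChain
    query_interval: tuple[int, int]
    identity_pct: float


@dataclass(frozen=True)
class SSString:
    """Per-query-residue secondary-structure states over {A, B, -, X}."""

    states: str
    source_label: str
    covered_interval: tuple[int, int]

    def __post_init__(self) -> None:
        bad = set(self.states) - set("AB-X")
        if bad:
            raise ValueError(f"invalid state characters: {sorted(bad)}")
        lo, hi = self.covered_interval
        if not 1 <= lo <= hi <= len(self.states):
            raise ValueError("covered_interval outside query bounds")
        outside = self.states[: lo - 1] + self.states[hi:]
        if set(outside) - {"X"}:
            raise ValueError("states outside covered_interval must be X")


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def read_structure_chain(
    path: str | Path, chain_id: str | None = None, structure_id: str | None = None
) -> StructureChain:
    """Read backbone coordinates for one chain from a PDB-format file.

    Uses the first model only and altloc blank-or-'A' atoms only. When
    ``chain_id`` is None the first chain containing amino acids is taken.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    chains = [ch for ch in model if ch.name == chain_id] if chain_id else list(model)
    for chain in chains:
        residues = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            backbone = {}
            for atom in res:
                if atom.altloc not in ("", " ", "\x00", "A"):
                    continue
                if atom.name in BACKBONE_ATOMS and atom.name not in backbone:
                    backbone[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
            if backbone:
                residues.append(
                    Residue(
                        seq_index=res.seqid.num,
                        amino_acid=_one_letter(res.name),
                        backbone=backbone,
                    )
                )
        if residues:
            return StructureChain(
                structure_id=structure_id or Path(path).stem,
                chain_id=chain.name,
                residues=tuple(residues),
            )
    raise ValueError(f"{path}: no amino-acid residues in requested chain")


def _amide_hydrogens(chain: StructureChain) -> list[np.ndarray | None]:
    """Rebuild amide H from the preceding peptide plane; None if undonatable.

    The H sits 1.0 Angstrom from N along the direction of the previous C=O
    bond (from O towards C). The first residue, prolines, residues with an
    incomplete backbone and residues after a chain break get None.
    """
    hs: list[np.ndarray | None] = [None] * len(chain.residues)
    for i in range(1, len(chain.residues)):
        res, prev = chain.residues[i], chain.residues[i - 1]
        if res.amino_acid == "P":
            continue
        if "N" not in res.backbone or "C" not in prev.backbone or "O" not in prev.backbone:
            continue
        if float(np.linalg.norm(res.backbone["N"] - prev.backbone["C"])) > PEPTIDE_BOND_MAX:
            continue
        direction = prev.backbone["C"] - prev.backbone["O"]
        norm = float(np.linalg.norm(direction))
        if norm == 0:
            continue
        hs[i] = res.backbone["N"] + direction / norm
    return hs


def _hbond_energy(
    acceptor: Residue, donor: Residue, donor_h: np.ndarray | None
) -> float:
    """Kabsch-Sander energy of C=O(acceptor) ... H-N(donor); +inf if undefined."""
    if donor_h is None or not {"C", "O"} <= acceptor.backbone.keys():
        return math.inf
    if "N" not in donor.backbone:
        return math.inf
    c, o = acceptor.backbone["C"], acceptor.backbone["O"]
    n, h = donor.backbone["N"], donor_h
    r_on = float(np.linalg.norm(o - n))
    r_ch = float(np.linalg.norm(c - h))
    r_oh = float(np.linalg.norm(o - h))
    r_cn = float(np.linalg.norm(c - n))
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # atom clash: undefined
        return math.inf
    return HBOND_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(chain: StructureChain) -> np.ndarray:
    """bonds[i, j] True when C=O of residue i accepts the amide H of residue j."""
    n = len(chain.residues)
    hs = _amide_hydrogens(chain)
    bonds = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 2:
                continue
            e = _hbond_energy(chain.residues[i], chain.residues[j], hs[j])
            bonds[i, j] = e < HBOND_ENERGY_CUTOFF
    return bonds


def assign_secondary_structure(chain: StructureChain) -> str:
    """Three-state string over {H, E, -}, one char per chain residue.

    Residues with missing backbone atoms are forced '-' (they cannot take
    part in any hydrogen bond we can evaluate) and reported via a warning.
    """
    n = len(chain.residues)
    if sum(1 for r in chain.residues if r.complete) < 5:
        raise ValueError("need at least 5 residues with a complete backbone")
    incomplete = [r.seq_index for r in chain.residues if not r.complete]
    if incomplete:
        warnings.warn(
            f"{chain.structure_id}: residues {incomplete} missing backbone "
            "atoms; forced to '-'",
            stacklevel=2,
        )
    bonds = _hbond_matrix(chain)

    states = ["-"] * n

    # alpha helix: two consecutive 4-turns at i-1 and i make i..i+3 helical
    turn4 = [i + 4 < n and bonds[i, i + 4] for i in range(n)]
    for i in range(1, n):
        if turn4[i - 1] and turn4[i]:
            for k in range(i, min(i + 4, n)):
                states[k] = "H"

    # bridges
    par: set[tuple[int, int]] = set()
    anti: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 3, n):
            if (
                (0 < i and i + 1 < n and bonds[i - 1, j] and bonds[j, i + 1])
                or (0 < j and j + 1 < n and bonds[j - 1, i] and bonds[i, j + 1])
            ):
                par.add((i, j))
            if (bonds[i, j] and bonds[j, i]) or (
                0 < i and j + 1 < n and 0 < j and i + 1 < n
                and bonds[i - 1, j + 1] and bonds[j - 1, i + 1]
            ):
                anti.add((i, j))

    # ladders: runs of consecutive bridges; length >= 2 marks strand (E),
    # an isolated bridge collapses to '-'
    strand: set[int] = set()
    for bridges, step in ((par, 1), (anti, -1)):
        for (i, j) in bridges:
            if (i + 1, j + step) in bridges or (i - 1, j - step) in bridges:
                strand.add(i)
                strand.add(j)
    for i in strand:
        if states[i] != "H":  # helix takes priority on overlap
            states[i] = "E"

    for i, res in enumerate(chain.residues):
        if not res.complete:
            states[i] = "-"
    return "".join(states)


_SS_TO_QUERY = {"H": "A", "E": "B", "-": "-"}


def map_structure_to_query(
    match: StructureMatch, query: ProteinSequence
) -> SSString:
    """Project a matched chain's secondary structure onto the query.

    The chain's modelled sequence is globally aligned (free end gaps) to the
    query interval; helix maps to A, strand to B, coil to '-'; query positions
    aligned to gaps -- residues absent from the coordinates -- or lying outside
    the interval are X.
    """
    lo, hi = match.query_interval
    if not 1 <= lo <= hi <= len(query.residues):
        raise ValueError("query_interval outside query bounds")
    sub_query = query.residues[lo - 1 : hi]
    ss = assign_secondary_structure(match.chain)
    aln = needleman_wunsch(match.chain.sequence, sub_query, free_end_gaps=True)

    states = ["X"] * len(query.residues)
    qi = lo - 1  # 0-based query cursor
    ci = 0  # chain cursor
    for a, b in zip(aln.aligned_a, aln.aligned_b):
        if b != "-":
            if a != "-":
                states[qi] = _SS_TO_QUERY[ss[ci]]
            qi += 1
        if a != "-":
            ci += 1
    return SSString(
        states="".join(states),
        source_label=match.chain.structure_id,
        covered_interval=match.query_interval,
    )


@dataclass(frozen=True)
class StructureSeqRecord:
    structure_id: str
    chain_id: str
    sequence: str


class StructureSequenceDatabase:
    """Sequences of structure chains, FASTA headers in the ``ID_CHAIN`` dialect."""

    def __init__(self, records: Sequence[StructureSeqRecord]):
        self.records = tuple(records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "StructureSequenceDatabase":
        from Bio import SeqIO

        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id
            if "_" in name:
                sid, chain = name.rsplit("_", 1)
            else:
                sid, chain = name, "A"
            records.append(
                StructureSeqRecord(
                    structure_id=sid,
                    chain_id=chain,
                    sequence=str(rec.seq).upper(),
                )
            )
        if not records:
            raise ValueError(f"{path}: empty structure-sequence database")
        return cls(records)


ChainLoader = Callable[[StructureSeqRecord], StructureChain]


def directory_chain_loader(directory: str | Path) -> ChainLoader:
    """Load ``<structure_id>.pdb`` files from one directory."""
    directory = Path(directory)

    def load(rec: StructureSeqRecord) -> StructureChain:
        return read_structure_chain(
            directory / f"{rec.structure_id}.pdb",
            chain_id=rec.chain_id,
            structure_id=rec.structure_id,
        )

    return load


def _best_segment_match(
    segment_seq: str, db: StructureSequenceDatabase
) -> tuple[StructureSeqRecord, float, object] | None:
    best = None
    for rec in db.records:
        aln = smith_waterman(segment_seq, rec.sequence)
        if aln.columns == 0:
            continue
        key = (-aln.score, rec.structure_id, rec.chain_id)
        if best is None or key < best[0]:
            best = (key, rec, aln)
    if best is None:
        return None
    _, rec, aln = best
    return rec, identity_pct(aln), aln


def _uncovered_segments(
    query_len: int, covered: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    mask = np.zeros(query_len, dtype=bool)
    for lo, hi in covered:
        mask[lo - 1 : hi] = True
    segments = []
    start = None
    for i in range(query_len):
        if not mask[i] and start is None:
            start = i
        elif mask[i] and start is not None:
            segments.append((start + 1, i))
            start = None
    if start is not None:
        segments.append((start + 1, query_len))
    return segments


def recursive_structure_search(
    query: ProteinSequence,
    structdb: StructureSequenceDatabase,
    settings: FilterSettings,
    load_chain: ChainLoader,
) -> list[SSString]:
    """Cover the query with structure matches, re-searching large gaps.

    The full query is searched first; afterwards every uncovered segment of
    at least 20 residues is re-searched until none remains or no segment
    yields a new above-threshold match. Segments whose best match falls below
    the identity threshold (or whose coordinates cannot be loaded) are marked
    exhausted so the iteration terminates. Coverage is tracked on searched
    intervals, so X positions inside an accepted match still count as covered.
    """
    if not structdb.records:
        raise ValueError("structure-sequence database is empty")
    results: list[SSString] = []
    covered: list[tuple[int, int]] = []
    exhausted: list[tuple[int, int]] = []
    qlen = len(query.residues)
    queue: list[tuple[int, int]] = [(1, qlen)]

    while queue:
        lo, hi = queue.pop(0)
        found = _best_segment_match(query.residues[lo - 1 : hi], structdb)
        accepted = False
        if found is not None:
            rec, ident, aln = found
            # a match must span at least the recursion granularity (or the
            # whole segment, if shorter) -- tiny high-identity local matches
            # carry no structural information and would never terminate usefully
            min_span = min(RECURSION_MIN_SEGMENT, hi - lo + 1)
            if ident >= settings.lower_identity_pct and aln.a_end - aln.a_start >= min_span:
                interval = (lo + aln.a_start, lo + aln.a_end - 1)
                try:
                    chain = load_chain(rec)
                    match = StructureMatch(
                        chain=chain, query_interval=interval, identity_pct=ident
                    )
                    results.append(map_structure_to_query(match, query))
                    covered.append(interval)
                    accepted = True
                except (OSError, ValueError) as exc:
                    warnings.warn(
                        f"structure {rec.structure_id} rejected: {exc}",
                        stacklevel=2,
                    )
        if not accepted:
            exhausted.append((lo, hi))
        queue = [
            seg
            for seg in _uncovered_segments(qlen, covered)
            if seg[1] - seg[0] + 1 >= RECURSION_MIN_SEGMENT
            and not any(e[0] <= seg[0] and seg[1] <= e[1] for e in exhausted)
        ]
    if not results:
        warnings.warn("no structure match found for query", stacklevel=2)
    return results
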