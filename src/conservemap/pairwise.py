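"""Affine-gap pairwise alignment engine (Gotoh dynamic programming).

Scoring follows protein-BLAST conventions: BLOSUM62 substitution scores with
a gap of length *k* costing ``GAP_OPEN + k * GAP_EXTEND`` (11 + k by default),
i.e. the first gap residue costs 12 and each further residue 1.

Local (Smith-Waterman) and global (Needleman-Wunsch, optionally with free end
gaps) variants share the same scoring model so that database search, guide-tree
distances and structure-to-query mapping are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

#: Closed scoring alphabet: the 20 standard residues plus X for anything else.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

#: BLAST protein defaults: gap of length k costs GAP_OPEN + k * GAP_EXTEND.
GAP_OPEN = 11
GAP_EXTEND = 1

_FIRST = GAP_OPEN + GAP_EXTEND  # cost of opening a gap of length 1
_NEG = -(10 ** 9)


def _build_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            mat[i, j] = int(blosum[a][b])
    return mat


SCORE_MATRIX = _build_matrix()

_ENCODE = np.full(128, ALPHABET.index("X"), dtype=np.int64)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as indices into :data:`SCORE_MATRIX`.

    Characters outside the alphabet map to X.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _ENCODE[arr]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored pairwise alignment with explicit gapped strings.

    ``a_start``/``a_end`` are 0-based half-open coordinates of the aligned
    region within each input (the full sequences for global alignments).
    """

    score: int
    aligned_a: str
    aligned_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def identities(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )


def identity_pct(aln: PairwiseAlignment) -> float:
    """Percent identity over all alignment columns, gaps included.

    Raises ``ValueError`` on a zero-column alignment.
    """
    if aln.columns == 0:
        raise ValueError("cannot compute identity of a zero-column alignment")
    return 100.0 * aln.identities / aln.columns


def _traceback(ptr_h, ptr_e, ptr_f, a, b, i, j, local: bool):
    """Walk backpointers from (i, j) in state H; returns gapped strings + start."""
    out_a: list[str] = []
    out_b: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            move = ptr_h[i, j]
            if move == 0:  # local start / global origin
                break
            if move == 1:  # diagonal
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif move == 2:  # came from E (gap in a / consumes b)
                state = "E"
            else:  # came from F (gap in b / consumes a)
                state = "F"
        elif state == "E":
            out_a.append("-")
            out_b.append(b[j - 1])
            if ptr_e[i, j] == 0:
                state = "H"
            j -= 1
        else:  # F
            out_a.append(a[i - 1])
            out_b.append("-")
            if ptr_f[i, j] == 0:
                state = "H"
            i -= 1
        if local and state == "H" and ptr_h[i, j] == 0:
            break
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def smith_waterman(a: str, b: str) -> PairwiseAlignment:
    """Optimal local alignment of ``a`` vs ``b`` under the module's scoring."""
    ea, eb = encode(a), encode(b)
    n, m = len(ea), len(eb)
    sub = SCORE_MATRIX[ea][:, eb] if n and m else np.zeros((n, m), dtype=np.int64)

    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)

    for i in range(1, n + 1):
        Hi, Hm = H[i], H[i - 1]
        Ei = E[i]
        row = sub[i - 1]
        for j in range(1, m + 1):
            e_open = Hi[j - 1] - _FIRST
            e_ext = Ei[j - 1] - GAP_EXTEND
            if e_ext > e_open:
                Ei[j] = e_ext
                ptr_e[i, j] = 1
            else:
                Ei[j] = e_open
            f_open = Hm[j] - _FIRST
            f_ext = F[i - 1, j] - GAP_EXTEND
            if f_ext > f_open:
                F[i, j] = f_ext
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_open
            diag = Hm[j - 1] + row[j - 1]
            best, move = 0, 0
            if diag > best:
                best, move = diag, 1
            if Ei[j] > best:
                best, move = Ei[j], 2
            if F[i, j] > best:
                best, move = F[i, j], 3
            Hi[j] = best
            ptr_h[i, j] = move

    end = np.unravel_index(int(np.argmax(H)), H.shape)
    score = int(H[end])
    aligned_a, aligned_b, i0, j0 = _traceback(
        ptr_h, ptr_e, ptr_f, a, b, int(end[0]), int(end[1]), local=True
    )
    return PairwiseAlignment(
        score=score,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        a_start=i0,
        a_end=int(end[0]),
        b_start=j0,
        b_end=int(end[1]),
    )


def needleman_wunsch(a: str, b: str, free_end_gaps: bool = False) -> PairwiseAlignment:
    """Optimal global alignment; with ``free_end_gaps`` terminal gaps cost 0.

    The free-end variant (semi-global / overlap alignment) is used to map a
    structure chain onto a query interval without penalising overhangs.
    """
    ea, eb = encode(a), encode(b)
    n, m = len(ea), len(eb)
    sub = SCORE_MATRIX[ea][:, eb] if n and m else np.zeros((n, m), dtype=np.int64)

    H = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)

    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = 0 if free_end_gaps else -(GAP_OPEN + j * GAP_EXTEND)
        H[0, j] = E[0, j]
        ptr_h[0, j] = 2
        ptr_e[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        F[i, 0] = 0 if free_end_gaps else -(GAP_OPEN + i * GAP_EXTEND)
        H[i, 0] = F[i, 0]
        ptr_h[i, 0] = 3
        ptr_f[i, 0] = 1 if i > 1 else 0

    for i in range(1, n + 1):
        Hi, Hm = H[i], H[i - 1]
        Ei = E[i]
        row = sub[i - 1]
        last_row = free_end_gaps and i == n
        for j in range(1, m + 1):
            ext = 0 if (last_row and free_end_gaps) else GAP_EXTEND
            e_open = Hi[j - 1] - (0 if last_row else _FIRST)
            e_ext = Ei[j - 1] - ext
            if e_ext > e_open:
                Ei[j] = e_ext
                ptr_e[i, j] = 1
            else:
                Ei[j] = e_open
                ptr_e[i, j] = 0
            last_col = free_end_gaps and j == m
            f_open = Hm[j] - (0 if last_col else _FIRST)
            f_ext = F[i - 1, j] - (0 if last_col else GAP_EXTEND)
            if f_ext > f_open:
                F[i, j] = f_ext
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_open
                ptr_f[i, j] = 0
            diag = Hm[j - 1] + row[j - 1]
            best, move = diag, 1
            if Ei[j] > best:
                best, move = Ei[j], 2
            if F[i, j] > best:
                best, move = F[i, j], 3
            Hi[j] = best
            ptr_h[i, j] = move

    aligned_a, aligned_b, _, _ = _traceback(ptr_h, ptr_e, ptr_f, a, b, n, m, local=False)
    return PairwiseAlignment(
        score=int(H[n, m]),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        a_start=0,
        a_end=n,
        b_start=0,
        b_end=m,
    )
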