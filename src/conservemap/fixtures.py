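"""Synthetic inputs with known ground truth for fully offline testing.

Two generators:

* protein families -- a random query plus per-species "orthologs" produced by
  BLOSUM62-biased point substitution to a target percent identity (optionally
  truncated or extended), and shuffled-composition decoys, all behind an
  explicit seed;
* idealised backbone coordinate files -- an alpha helix (phi = -57, psi = -47)
  or an antiparallel beta hairpin (strands at phi = -139, psi = +135 joined by
  a four-residue turn) built from standard peptide geometry, enough for
  hydrogen-bond patterns to form without side chains.

Everything here is synthetic stand-in data: families undergo point
substitution only (no indel process, no site-rate heterogeneity) and the
coordinate files are idealised geometry, not experimental structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .pairwise import SCORE_MATRIX, encode
from .species_db import (
    ProteinSequence,
    SpeciesDatabase,
    SpeciesRegistry,
)
from .structure_annotation import Residue, StructureChain

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Standard peptide backbone geometry (bond lengths in Angstrom, angles deg).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0


@dataclass(frozen=True)
class FamilySpec:
    """Plan for one synthetic ortholog family."""

    query_length: int = 150
    species_plan: tuple[tuple[str, float, float], ...] = ()
    decoys_per_species: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.query_length < 10:
            raise ValueError("query_length must be at least 10")
        for name, ident, factor in self.species_plan:
            if not 0.0 <= ident <= 100.0:
                raise ValueError(f"{name}: target identity out of [0, 100]")
            if factor <= 0:
                raise ValueError(f"{name}: length_factor must be positive")
            if ident == 100.0 and factor != 1.0:
                raise ValueError(
                    f"{name}: identity 100 is infeasible with length_factor != 1"
                )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _biased_substitution(rng: np.random.Generator, original: str) -> str:
    """Draw a replacement residue with probability rising in BLOSUM62 score."""
    i = int(encode(original)[0])
    scores = SCORE_MATRIX[i, :20].astype(float)
    scores[i] = -np.inf  # never the identity
    weights = np.exp(scores / 2.0)
    weights /= weights.sum()
    return AA20[int(rng.choice(20, p=weights))]


def _mutate_to_identity(
    rng: np.random.Generator, query: str, target_identity_pct: float
) -> tuple[str, float]:
    n = len(query)
    n_sub = int(round((100.0 - target_identity_pct) / 100.0 * n))
    positions = rng.choice(n, size=n_sub, replace=False)
    seq = list(query)
    for p in positions:
        seq[p] = _biased_substitution(rng, seq[p])
    realized = 100.0 * (n - n_sub) / n
    return "".join(seq), realized


def _decoy(rng: np.random.Generator, query: str) -> str:
    """Shuffled-composition sequence; positional identity to query < 25%."""
    letters = np.array(list(query))
    for _ in range(50):
        rng.shuffle(letters)
        ident = 100.0 * float(np.mean(letters == np.array(list(query)))) if len(query) else 0.0
        if ident < 25.0:
            return "".join(letters)
    raise RuntimeError("could not shuffle a decoy below 25% identity")


def generate_family(
    spec: FamilySpec,
) -> tuple[ProteinSequence, SpeciesRegistry, dict[str, float]]:
    """Build (query, registry, truth) from a :class:`FamilySpec`.

    ``truth`` maps species name to the realized substitution identity of its
    planted ortholog (percentage of unsubstituted query positions, measured
    before any truncation/extension). Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    query_seq = _random_sequence(rng, spec.query_length)
    query = ProteinSequence(id="QUERY_1", description="synthetic query", residues=query_seq)

    databases = []
    truth: dict[str, float] = {}
    for name, target_ident, factor in spec.species_plan:
        ortholog_seq, realized = _mutate_to_identity(rng, query_seq, target_ident)
        new_len = max(1, int(round(spec.query_length * factor)))
        if new_len < len(ortholog_seq):
            ortholog_seq = ortholog_seq[:new_len]
        elif new_len > len(ortholog_seq):
            ortholog_seq += _random_sequence(rng, new_len - len(ortholog_seq))
        truth[name] = realized

        tag = name.replace(" ", "_")
        records = [
            ProteinSequence(
                id=f"{tag}_ORTH", description=f"{name} planted ortholog",
                residues=ortholog_seq,
            )
        ]
        for d in range(spec.decoys_per_species):
            records.append(
                ProteinSequence(
                    id=f"{tag}_DEC{d}", description=f"{name} decoy {d}",
                    residues=_decoy(rng, query_seq),
                )
            )
        databases.append(
            SpeciesDatabase(
                species_name=name,
                taxonomy_path=("Synthetic",),
                sequences=tuple(records),
            )
        )
    registry = SpeciesRegistry(databases=tuple(databases))
    return query, registry, truth


def write_registry_tree(registry: SpeciesRegistry, root: str | Path) -> None:
    """Serialize a registry as a taxonomy-shaped FASTA tree under ``root``."""
    root = Path(root)
    for db in registry.databases:
        d = root.joinpath(*db.taxonomy_path)
        d.mkdir(parents=True, exist_ok=True)
        path = d / (db.species_name.replace(" ", "_") + ".fasta")
        with open(path, "w") as fh:
            for rec in db.sequences:
                fh.write(f">{rec.id} {rec.description}\n")
                for k in range(0, len(rec.residues), 60):
                    fh.write(rec.residues[k : k + 60] + "\n")


# --- idealised backbone geometry ------------------------------------------


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """NeRF: position a new atom given three predecessors and internal coords."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    torsions: Sequence[tuple[float, float]], omega: float = 180.0
) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for a chain with given (phi, psi) per residue.

    phi of the first residue and psi of the last are irrelevant to atom
    placement beyond the chain ends and are accepted for uniformity.
    """
    n_res = len(torsions)
    residues: list[dict[str, np.ndarray]] = []
    # seed the first three atoms
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    angle = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(angle), np.sin(angle), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = torsions[i - 1][1]
        n_new = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_new = _place_atom(prev["CA"], prev["C"], n_new, BOND_N_CA, ANGLE_C_N_CA, omega)
        phi = torsions[i][0]
        c_new = _place_atom(prev["C"], n_new, ca_new, BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n_new, "CA": ca_new, "C": c_new})
    # carbonyl oxygens: in the peptide plane, anti to the next amide N
    for i, res in enumerate(residues):
        if i + 1 < n_res:
            next_n = residues[i + 1]["N"]
            res["O"] = _place_atom(
                next_n, res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, 180.0
            )
        else:
            psi = torsions[i][1]
            res["O"] = _place_atom(
                res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
            )
    return residues


def _chain_from_backbone(
    backbone: list[dict[str, np.ndarray]],
    structure_id: str,
    sequence: str | None = None,
) -> StructureChain:
    seq = sequence or "A" * len(backbone)
    residues = tuple(
        Residue(seq_index=i + 1, amino_acid=seq[i], backbone=dict(atoms))
        for i, atoms in enumerate(backbone)
    )
    return StructureChain(structure_id=structure_id, chain_id="A", residues=residues)


def _fit_antiparallel(strand_a, strand_b):
    """Rigid-fit strand B against strand A into an antiparallel H-bond register.

    Pairs residue k of A (from the C-terminal end) with residue k of B and
    asks alternating N-O distances to sit at hydrogen-bond range (2.9 A);
    deterministic (fixed start point, least squares).
    """
    sa = len(strand_a)

    def apply(params, atoms):
        rot = Rotation.from_rotvec(params[:3])
        return {k: rot.apply(v) + params[3:] for k, v in atoms.items()}

    def residuals(params):
        placed = [apply(params, r) for r in strand_b]
        out = []
        for k in range(sa):
            ra = strand_a[sa - 1 - k]
            rb = placed[k]
            if k % 2 == 0:  # directly H-bonded pair
                out.append(np.linalg.norm(ra["O"] - rb["N"]) - 2.9)
                out.append(np.linalg.norm(ra["N"] - rb["O"]) - 2.9)
            out.append(np.linalg.norm(ra["CA"] - rb["CA"]) - 4.9)
        return out

    x0 = np.array([0.0, 0.0, np.pi, 0.0, 5.0, 0.0])
    fit = least_squares(residuals, x0, method="lm", max_nfev=5000)
    return [apply(fit.x, r) for r in strand_b]


def generate_ideal_structure(
    kind: str, length: int, sequence: str | None = None
) -> StructureChain:
    """An idealised helix or antiparallel hairpin backbone (poly-Ala default).

    ``kind`` is ``"helix"`` or ``"hairpin"``; ``length`` is the total residue
    count (at least 6; hairpins need at least 12 so each strand has 4+
    residues around the 4-residue turn). An optional ``sequence`` of matching
    length labels the residues, letting fixtures tie idealised coordinates to
    a given query segment.
    """
    if length < 6:
        raise ValueError("length must be at least 6")
    if sequence is not None and len(sequence) != length:
        raise ValueError("sequence length must equal length")
    if kind == "helix":
        backbone = build_backbone([(HELIX_PHI, HELIX_PSI)] * length)
        return _chain_from_backbone(backbone, f"HLX{length}", sequence)
    if kind == "hairpin":
        if length < 12:
            raise ValueError("hairpin needs at least 12 residues")
        turn_len = 4
        s_len = (length - turn_len) // 2
        extra = length - turn_len - 2 * s_len
        strand_a = build_backbone([(STRAND_PHI, STRAND_PSI)] * (s_len + extra))
        strand_b0 = build_backbone([(STRAND_PHI, STRAND_PSI)] * s_len)
        strand_b = _fit_antiparallel(strand_a, strand_b0)
        # turn backbone: linear interpolation between the strand ends; the
        # turn is connective tissue, not an assignment target
        start = strand_a[-1]["C"]
        end = strand_b[0]["N"]
        turn = []
        for t in range(turn_len):
            f0 = (t + 0.5) / turn_len
            lift = np.array([0.0, 0.0, 3.0 * np.sin(np.pi * f0)])
            base = start + (end - start) * f0 + lift
            turn.append(
                {
                    "N": base,
                    "CA": base + np.array([0.9, 0.9, 0.0]),
                    "C": base + np.array([1.8, 0.3, 0.3]),
                    "O": base + np.array([2.2, -0.8, 0.3]),
                }
            )
        backbone = strand_a + turn + strand_b
        return _chain_from_backbone(backbone, f"HPN{length}", sequence)
    raise ValueError(f"unknown kind {kind!r}")


THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


def write_chain_pdb(chain: StructureChain, path: str | Path) -> None:
    """Serialize a backbone chain as a single-model PDB file via gemmi."""
    st = gemmi.Structure()
    st.name = chain.structure_id
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain.chain_id)
    for res in chain.residues:
        gres = gemmi.Residue()
        gres.name = THREE_LETTER.get(res.amino_acid, "ALA")
        gres.seqid = gemmi.SeqId(res.seq_index, " ")
        for name, pos in res.backbone.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*[round(float(x), 3) for x in pos])
            atom.occ = 1.0
            atom.b_iso = 20.0
            gres.add_atom(atom)
        gchain.add_residue(gres)
    model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_fixture_set(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a ready-to-use db-root tree, struct-db FASTA and toy PDB files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = FamilySpec(
        query_length=150,
        species_plan=(
            ("Homo sapiens", 95.0, 1.0),
            ("Mus musculus", 90.0, 1.0),
            ("Danio rerio", 80.0, 1.0),
            ("Xenopus laevis", 75.0, 1.0),
            ("Drosophila melanogaster", 65.0, 1.0),
            ("Saccharomyces cerevisiae", 55.0, 1.0),
        ),
        decoys_per_species=2,
        seed=seed,
    )
    query, registry, _ = generate_family(spec)
    db_root = out / "db_root"
    write_registry_tree(registry, db_root)
    query_path = out / "query.fasta"
    with open(query_path, "w") as fh:
        fh.write(f">{query.id} {query.description}\n")
        for k in range(0, len(query.residues), 60):
            fh.write(query.residues[k : k + 60] + "\n")

    struct_dir = out / "structures"
    struct_dir.mkdir(exist_ok=True)
    helix = generate_ideal_structure("helix", 30, query.residues[:30])
    hairpin = generate_ideal_structure("hairpin", 20, query.residues[30:50])
    write_chain_pdb(helix, struct_dir / f"{helix.structure_id}.pdb")
    write_chain_pdb(hairpin, struct_dir / f"{hairpin.structure_id}.pdb")
    struct_db = struct_dir / "struct_db.fasta"
    with open(struct_db, "w") as fh:
        # chain sequences tied to query segments so searches can succeed:
        # label the helix with the first 30 query residues, the hairpin with
        # the next 20 (synthetic pairing of sequence to idealised backbone)
        fh.write(f">{helix.structure_id}_A synthetic helix\n{query.residues[:30]}\n")
        fh.write(
            f">{hairpin.structure_id}_A synthetic hairpin\n{query.residues[30:50]}\n"
        )
    return {
        "db_root": db_root,
        "query": query_path,
        "struct_db": struct_db,
        "struct_dir": struct_dir,
    }
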