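"""Per-species protein databases laid out as a taxonomy-shaped directory tree.

Each FASTA file under the root is one species database; its relative directory
path is the species' taxonomy path (e.g. ``Fungi/Saccharomyces_cerevisiae.fasta``
gives taxonomy ``[Fungi]``). The registry mirrors the tree and carries an
include/exclude set so problematic species can be dropped and a run repeated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

from .pairwise import ALPHABET

_ALLOWED = set(ALPHABET)

#: Residue codes outside the 20-letter scoring alphabet collapse to X.
NONSTANDARD_TO_X = str.maketrans({c: "X" for c in "BZUOJ*"})

FASTA_SUFFIXES = {".fasta", ".fa", ".faa"}


class RegistryError(ValueError):
    """Raised for unloadable roots or unknown species names."""


@dataclass(frozen=True)
class ProteinSequence:
    """A single protein record: accession, free-text description, residues.

    Residues are uppercase over the 20 standard letters plus X; non-standard
    codes (B, Z, U, O, J, ``*``) are collapsed to X at construction.
    """

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        cleaned = self.residues.upper().translate(NONSTANDARD_TO_X)
        object.__setattr__(self, "residues", cleaned)
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SpeciesDatabase:
    """All protein sequences of one species plus its taxonomy path."""

    species_name: str
    taxonomy_path: tuple[str, ...]
    sequences: tuple[ProteinSequence, ...]

    def __post_init__(self) -> None:
        if not self.species_name:
            raise ValueError("species_name must be non-empty")
        if len(self.taxonomy_path) < 1:
            raise ValueError("taxonomy_path must have depth >= 1")
        if not self.sequences:
            raise ValueError(f"database {self.species_name!r} has no sequences")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate accessions in {self.species_name!r}")


@dataclass(frozen=True)
class SpeciesRegistry:
    """An ordered collection of species databases with an exclusion set."""

    databases: tuple[SpeciesDatabase, ...]
    excluded: frozenset[str] = field(default_factory=frozenset)
    load_report: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [db.species_name for db in self.databases]
        if len(set(names)) != len(names):
            raise ValueError("species_name must be unique across the registry")
        unknown = self.excluded - set(names)
        if unknown:
            raise RegistryError(
                f"excluded species not in registry: {sorted(unknown)}"
            )

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(db.species_name for db in self.databases)

    def active(self) -> Iterator[SpeciesDatabase]:
        """Databases not currently excluded, in registry order."""
        for db in self.databases:
            if db.species_name not in self.excluded:
                yield db


def _species_name_from_stem(stem: str) -> str:
    return stem.replace("_", " ")


def _load_fasta(path: Path, taxonomy: tuple[str, ...]) -> SpeciesDatabase:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinSequence(
                id=rec.id,
                description=rec.description,
                residues=str(rec.seq),
            )
        )
    if not records:
        raise ValueError(f"{path} contains no records")
    return SpeciesDatabase(
        species_name=_species_name_from_stem(path.stem),
        taxonomy_path=taxonomy if taxonomy else ("",),
        sequences=tuple(records),
    )


def load_registry(root_dir: str | Path) -> SpeciesRegistry:
    """Load every FASTA under ``root_dir`` into a :class:`SpeciesRegistry`.

    One FASTA file = one species; species name is the file stem with
    underscores replaced by spaces. Files are loaded in lexicographic order of
    their relative paths so two loads of the same tree are element-wise equal.
    Unreadable or malformed files are skipped with a warning recorded in the
    registry's load report; loading zero databases is a hard error.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise RegistryError(f"database root {root} does not exist")
    paths = sorted(
        p for p in root.rglob("*") if p.is_file() and p.suffix.lower() in FASTA_SUFFIXES
    )
    databases: list[SpeciesDatabase] = []
    report: list[str] = []
    for path in paths:
        rel = path.relative_to(root)
        taxonomy = tuple(rel.parts[:-1]) if len(rel.parts) > 1 else (root.name,)
        try:
            databases.append(_load_fasta(path, taxonomy))
        except Exception as exc:  # noqa: BLE001 - per-file skip is the contract
            msg = f"skipped {rel}: {exc}"
            report.append(msg)
            warnings.warn(msg, stacklevel=2)
    if not databases:
        raise RegistryError(f"no species databases loaded from {root}")
    return SpeciesRegistry(databases=tuple(databases), load_report=tuple(report))


def exclude_species(
    registry: SpeciesRegistry, names: Sequence[str]
) -> SpeciesRegistry:
    """Return a copy of ``registry`` with ``names`` added to the excluded set.

    Unknown names raise :class:`RegistryError` naming the offending string;
    the input registry is never modified. Idempotent and self-commuting.
    """
    known = set(registry.species_names)
    for name in names:
        if name not in known:
            raise RegistryError(f"unknown species name: {name!r}")
    return replace(registry, excluded=registry.excluded | set(names))
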