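"""End-to-end orchestration: search, align, annotate structure, emit scripts.

The four stages run in a fixed order -- best-hit ortholog search, progressive
alignment with conservation annotation, secondary-structure mapping (optional),
PyMOL script generation -- and all run products land in one output directory:

    outputs/<run_name>/
        <run_name>_alignment.txt     annotated alignment + run-report footer
        <run_name>_clustal.pml       discrete conservation-symbol colouring
        <run_name>_pctmatch.pml      continuous percent-match ramp
        <run_name>.log               per-run log (skips, rejections, notices)
        *.pdb                        copies of any structure files analysed

Nothing in the core path is stochastic, so two identical runs produce
byte-identical directories; outputs carry no timestamps for the same reason.
"""

from __future__ import annotations

import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from Bio import SeqIO

from .msa_conservation import (
    ConservationAnnotation,
    MultipleAlignment,
    QUERY_LABEL,
    annotate,
    build_alignment,
)
from .ortholog_search import FilterSettings, SearchHit, filter_hits, search_registry
from .projection import ColorScheme, apply_offset, continuous_script, discrete_script
from .species_db import (
    ProteinSequence,
    SpeciesRegistry,
    exclude_species,
    load_registry,
)
from .structure_annotation import (
    SSString,
    StructureMatch,
    StructureSequenceDatabase,
    directory_chain_loader,
    map_structure_to_query,
    read_structure_chain,
    recursive_structure_search,
)

BLOCK_WIDTH = 60
LABEL_WIDTH = 28


class PipelineError(RuntimeError):
    """A run-aborting condition with an actionable message."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs; mirrors the CLI flags one-to-one."""

    query: ProteinSequence
    db_root: Path
    run_name: str
    filters: FilterSettings = field(default_factory=FilterSettings)
    excluded_species: tuple[str, ...] = ()
    shade_family: str = "blue"
    residue_offset: int = 0
    struct_db: Path | None = None
    model_paths: tuple[Path, ...] = ()
    no_structure: bool = False
    out_root: Path = Path("outputs")

    def __post_init__(self) -> None:
        if not self.run_name:
            raise ValueError("run_name must be non-empty")
        if any(c in self.run_name for c in "/\\\0") or self.run_name in (".", ".."):
            raise ValueError(f"run_name {self.run_name!r} is not filesystem-safe")


@dataclass
class RunReport:
    """Settings echo, per-species dispositions, accession list, warnings."""

    settings: FilterSettings
    excluded_species: tuple[str, ...]
    shade_family: str
    dispositions: list[tuple[str, str]] = field(default_factory=list)
    accessions: list[tuple[str, str]] = field(default_factory=list)  # (species, id)
    structure_sources: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def footer_lines(self) -> list[str]:
        lines = [
            "",
            "=" * 70,
            "RUN SETTINGS",
            f"  lower identity threshold : {self.settings.lower_identity_pct:g} %",
            f"  upper identity threshold : {self.settings.upper_identity_pct:g} %",
            f"  length threshold         : {self.settings.length_threshold_pct:g} %",
            f"  shade family             : {self.shade_family}",
            "  excluded species         : "
            + (", ".join(self.excluded_species) if self.excluded_species else "none"),
            "",
            "SPECIES DISPOSITIONS",
        ]
        lines += [f"  {name}: {what}" for name, what in self.dispositions]
        lines += ["", "ACCESSIONS IN ALIGNMENT"]
        lines += [f"  {species}: {acc}" for species, acc in self.accessions]
        if self.structure_sources:
            lines += ["", "STRUCTURES ANALYSED"]
            lines += [f"  {s}" for s in self.structure_sources]
        if self.warnings:
            lines += ["", "WARNINGS"]
            lines += [f"  {w}" for w in self.warnings]
        return lines


def fetch_query(
    accession: str, resolver: Mapping[str, ProteinSequence] | Callable[[str], ProteinSequence]
) -> ProteinSequence:
    """Resolve an accession through a configured sequence resolver.

    The resolver is any mapping or callable from accession to sequence (tests
    and offline runs use a local FASTA-backed one); an unresolvable accession
    raises :class:`PipelineError` naming it.
    """
    try:
        if callable(resolver):
            return resolver(accession)
        return resolver[accession]
    except (KeyError, LookupError) as exc:
        raise PipelineError(f"could not resolve accession {accession!r}") from exc


def fasta_resolver(path: str | Path) -> dict[str, ProteinSequence]:
    """A resolver backed by a local FASTA file, keyed by record id."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = ProteinSequence(
            id=rec.id, description=rec.description, residues=str(rec.seq)
        )
    return out


def load_query(source: str | Path) -> ProteinSequence:
    """Accept an inline residue string or a path to a single-record FASTA."""
    path = Path(source)
    if path.exists():
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise PipelineError(f"{path} contains no FASTA records")
        rec = records[0]
        return ProteinSequence(id=rec.id, description=rec.description, residues=str(rec.seq))
    return ProteinSequence(id="QUERY", description="inline query", residues=str(source))


def _format_alignment(
    alignment: MultipleAlignment,
    annotation: ConservationAnnotation,
    ss_strings: Sequence[SSString],
) -> str:
    """CLUSTAL-style 60-column blocks with symbol, glyph and structure lines."""
    qcols = alignment.query_columns()
    n_cols = alignment.column_count

    # spread per-query-residue strings over alignment columns
    def spread(per_residue: str, fill: str = " ") -> str:
        out = [fill] * n_cols
        for k, col in enumerate(qcols):
            out[col] = per_residue[k]
        return "".join(out)

    glyph_line = spread(annotation.match_glyphs)
    ss_lines = [
        (f"[{ss.source_label}]", spread(ss.states))
        for ss in ss_strings
    ]

    blocks = []
    for start in range(0, n_cols, BLOCK_WIDTH):
        end = min(start + BLOCK_WIDTH, n_cols)
        chunk = []
        for label, row in alignment.rows:
            chunk.append(f"{label[:LABEL_WIDTH]:<{LABEL_WIDTH}}  {row[start:end]}")
        chunk.append(f"{'':<{LABEL_WIDTH}}  {annotation.symbols[start:end]}")
        chunk.append(f"{'% match':<{LABEL_WIDTH}}  {glyph_line[start:end]}")
        for label, line in ss_lines:
            chunk.append(f"{label[:LABEL_WIDTH]:<{LABEL_WIDTH}}  {line[start:end]}")
        blocks.append("\n".join(chunk))
    return "conservemap annotated alignment\n\n" + "\n\n".join(blocks) + "\n"


def run_pipeline(config: RunConfig) -> Path:
    """Execute all four stages and return the populated output directory."""
    report = RunReport(
        settings=config.filters,
        excluded_species=tuple(config.excluded_species),
        shade_family=config.shade_family,
    )
    log: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        registry = load_registry(config.db_root)
        if config.excluded_species:
            registry = exclude_species(registry, config.excluded_species)

        log.append(f"stage 1: ortholog search over {len(list(registry.active()))} species")
        hits = search_registry(config.query, registry)
        kept = filter_hits(hits, config.filters, len(config.query.residues))
        kept_names = {h.species_name for h in kept}
        for h in hits:
            if h.species_name in kept_names:
                disp = (
                    f"kept {h.hit.id} (identity {h.identity_pct:.1f} %, "
                    f"length {h.length_ratio_pct:.1f} %)"
                )
            else:
                disp = (
                    f"dropped {h.hit.id} (identity {h.identity_pct:.1f} %, "
                    f"length {h.length_ratio_pct:.1f} %)"
                )
            report.dispositions.append((h.species_name, disp))

        if len(kept) < 1:
            raise PipelineError(
                "fewer than 2 sequences would enter the alignment; lower the "
                "identity threshold or widen the length threshold"
            )

        log.append(f"stage 2: aligning query + {len(kept)} hits")
        alignment = build_alignment(config.query, kept)
        annotation = annotate(alignment)
        report.accessions = [(h.species_name, h.hit.id) for h in kept]

        ss_strings: list[SSString] = []
        used_structures: list[Path] = []
        if not config.no_structure:
            if config.struct_db is not None:
                log.append("stage 3: structure search")
                structdb = StructureSequenceDatabase.from_fasta(config.struct_db)
                loader = directory_chain_loader(Path(config.struct_db).parent)
                ss_strings.extend(
                    recursive_structure_search(
                        config.query, structdb, config.filters, loader
                    )
                )
                for ss in ss_strings:
                    used_structures.append(
                        Path(config.struct_db).parent / f"{ss.source_label}.pdb"
                    )
            for model_path in config.model_paths:
                chain = read_structure_chain(model_path, structure_id="AlphaFold")
                match = StructureMatch(
                    chain=chain,
                    query_interval=(1, len(config.query.residues)),
                    identity_pct=100.0,
                )
                ss_strings.append(map_structure_to_query(match, config.query))
                used_structures.append(Path(model_path))
            report.structure_sources = [ss.source_label for ss in ss_strings]
            if not ss_strings:
                log.append("stage 3: no structures annotated")
        else:
            log.append("stage 3: skipped (--no-structure)")

        log.append("stage 4: projection scripts")
        discrete = discrete_script(
            annotation,
            ColorScheme(config.shade_family, "discrete"),
            header=[
                f"conservemap run {config.run_name}: discrete conservation-symbol colours",
                f"shade family: {config.shade_family}",
            ],
        )
        continuous = continuous_script(
            annotation,
            ColorScheme(config.shade_family, "continuous"),
            header=[
                f"conservemap run {config.run_name}: percent-match colour ramp",
                f"shade family: {config.shade_family}",
            ],
        )
        if config.residue_offset:
            discrete = apply_offset(discrete, config.residue_offset)
            continuous = apply_offset(continuous, config.residue_offset)

        report.warnings = sorted({str(w.message) for w in caught})

    out_dir = Path(config.out_root) / config.run_name
    out_dir.mkdir(parents=True, exist_ok=True)
    alignment_text = _format_alignment(alignment, annotation, ss_strings)
    footer = "\n".join(report.footer_lines()) + "\n"
    (out_dir / f"{config.run_name}_alignment.txt").write_text(alignment_text + footer)
    (out_dir / f"{config.run_name}_clustal.pml").write_text(discrete.render())
    (out_dir / f"{config.run_name}_pctmatch.pml").write_text(continuous.render())
    for src in dict.fromkeys(used_structures):
        if Path(src).exists():
            shutil.copy(src, out_dir / Path(src).name)
    (out_dir / f"{config.run_name}.log").write_text("\n".join(log) + "\n")
    return out_dir
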