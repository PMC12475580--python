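# Methods

This note documents the models and procedures implemented in `conservemap`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Scoring model

All pairwise and profile alignment uses BLOSUM62 with affine gap costs in the
protein-BLAST convention: a gap of length *k* costs 11 + *k* (first gap
residue 12, each further residue 1). The scoring alphabet is the 20 standard
residues plus `X`; non-standard codes (B, Z, U, O, J, `*`) collapse to `X` at
load so the alphabet stays closed. Local (Smith–Waterman) and global
(Needleman–Wunsch, optionally with free end gaps) variants are implemented as
Gotoh three-state dynamic programming with full traceback.

## Ortholog search

Each species database contributes at most one hit: the sequence with the
maximal local-alignment score, ties broken lexicographically by accession.
Search acceleration is a 3-mer two-hit prefilter — a subject qualifies when
two non-overlapping exact 3-mer seeds fall on one diagonal within a 64-residue
span — after which candidates are scored by *exact* Smith–Waterman. Seeding
therefore decides which subjects are scored, never the score itself, and the
seeded search provably returns the same score as exhaustive alignment for any
subject it scores. Problems under 4096 matrix cells, or with either sequence
shorter than 40 residues, skip seeding: full dynamic programming is as fast
there as building a seed index. If the prefilter rejects every subject in a
database (possible when nothing in it resembles the query), the whole
database is scored exhaustively so the maximal-score contract still holds.

**Percent identity** is identities divided by all alignment columns, gaps
included (the `pident` convention). The alternative — identity over query
length — would conflate divergence with fragment length; fragments are
handled by the separate length window instead, which compares full unaligned
sequence lengths. Filter bounds are inclusive on the keep side: a hit at
exactly the lower identity threshold, or at exactly 80%/120% of the query
length under a 20% window, is kept.

| parameter | default | meaning |
|---|---|---|
| `lower_identity_pct` | 50 | identity floor, % — below it, hits are likely structural homologs rather than functional orthologs |
| `upper_identity_pct` | 100 | identity ceiling, % — lower it to shed near-duplicates that add no divergence signal |
| `length_threshold_pct` | 20 | symmetric length window, % of query length — drops fragments and fusions |

Both identity thresholds need per-protein tuning in practice: too high a
floor leaves too little divergence (everything looks conserved), too low
admits homologs that wash hotspots out. The defaults are starting points for
compact globular proteins.

## Progressive alignment

Pairwise identity distances (1 − identity fraction, from free-end-gap global
alignments) feed an average-linkage (UPGMA) guide tree; profiles are merged
in tree order. Profile–profile column scores are the expectation of the
substitution score over the two columns' residue frequencies (gap entries
contribute zero); gap costs are the pairwise ones, with end gaps free during
merges so truncated orthologs dock against the profile without distorting
terminal columns. The merge pattern inserts gap columns only, so every input
sequence — in particular the query — is reproduced exactly by ungapping its
row. Row order in the output equals input order. No attempt is made to
reproduce any particular aligner's position-specific gap heuristics
bit-for-bit; the contract is a deterministic alignment consistent with the
scoring model above.

## Conservation annotation

Column symbols follow the ClustalX strong/weak group convention:

- strong: STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW
- weak: CSA, ATV, SAG, STNK, STPA, SGND, SNDEQK, NDEQHK, NEQHRK, FVLIM, HFY

`*` requires an identical, gap-free column; `:` (resp. `.`) requires the
gap-free residue set to fit in one strong (resp. weak) group; anything else,
including any column containing a gap, is a space. Counting a gap as
non-conserved is deliberate: a deletion in a single admitted sequence already
wipes the symbol-line signal for that region, which is exactly the failure
mode that motivates the species-exclusion workflow.

Percent-match is computed per query-residue column as 100 × (non-query rows
whose residue equals the query's) / (all non-query rows). Rows gapped at the
column stay in the denominator as mismatches — the score then reflects how
much of the sampled taxonomy actually matches the query, not how much of the
locally alignable subset does. The display glyph bins are implemented exactly
as the output convention prints them, with uneven widths and `▄` serving both
70–79% and 90–99%:

| bin | 0–19 | 20–39 | 40–49 | 50–59 | 60–69 | 70–79 | 80–89 | 90–99 | 100 |
|---|---|---|---|---|---|---|---|---|---|
| glyph | ` ` | `-` | `━` | `▂` | `▃` | `▄` | `▅` | `▄` | `▆` |

The duplicated glyph is almost certainly a historical typo in the convention,
but the glyph string is a write-only annotation (nothing parses it back), so
it is reproduced as printed and flagged here for maintainers. The numeric
`match_pct` values, which the continuous colouring uses, are unaffected.

## Secondary-structure assignment

The assigner implements the Kabsch–Sander hydrogen-bond core. The amide
hydrogen is rebuilt on each nitrogen at 1.0 Å along the previous residue's
C→O direction reversed (first residue, prolines, and residues following a
chain break — peptide C–N distance > 2.5 Å — cannot donate). A hydrogen bond
from donor NH(j) to acceptor C=O(i) exists when

    E = 27.888 · (1/r(ON) + 1/r(CH) − 1/r(OH) − 1/r(CN)) < −0.5 kcal/mol.

Alpha helices are residues i…i+3 wherever two consecutive i→i+4 turns exist
(at i−1 and i); strands are residues in parallel or antiparallel bridge
ladders of length ≥ 2, with the standard bridge definitions. The collapse to
the three displayed states is conservative: only 4-helix → `A` and ladder
strand → `B`; 3₁₀/π helices, isolated bridges, turns and bends report as
`-` (unstructured), since the output vocabulary only speaks of alpha helices
and beta strands. Residues with incomplete backbones are forced `-` and
flagged; assignment requires at least 5 complete residues.

On the idealised fixture suite this assigner agrees 100% with an independent
reference implementation (mdtraj's DSSP, collapsed with the same rule); the
test suite asserts ≥ 95% to leave head-room for boundary-residue conventions
on less ideal geometry.

## Structure search and recursion

The structure-sequence database is a FASTA whose headers are `ID_CHAIN`;
coordinate files `<ID>.pdb` live beside it. The best chain for a query
segment is found with the same local-alignment machinery and accepted when
its identity meets the lower identity threshold *and* its alignment spans at
least 20 query residues (or the whole segment, when the segment is shorter) —
without the span floor, tiny high-identity local matches would "cover"
segments while carrying no structural information. The chain's *modelled*
sequence (from coordinates, not the header FASTA) is then globally aligned
(free end gaps) to the matched query interval; query positions aligned to a
chain residue inherit its state, positions aligned to gaps (residues absent
from the coordinates) or outside the interval become `X`.

Coverage is tracked on searched query intervals — `X` positions inside an
accepted match's interval count as covered, because the recursion is keyed on
what has been searched, not on modelled density. After each accepted match,
every uncovered segment of ≥ 20 residues is re-searched; a segment whose
best match falls below threshold (or whose coordinates cannot be loaded) is
marked exhausted and never re-queued, which guarantees termination: every
iteration either covers at least one new residue or exhausts a segment.
Segments shorter than 20 residues never trigger a search. User-supplied
models are registered under the source label `AlphaFold` and run through the
same assignment/mapping path; no network access exists anywhere in the core.

## Projection scripts

Both scripts are self-contained PyMOL command files: named colours are
defined in the header with `set_color` and applied with per-residue
`color <name>, resi <n>` commands, so replay needs no other state. Discrete
levels map `*`/`:`/`.`/space to dark/medium/light/neutral; the exact RGB
values per shade family are this package's own choice (the convention names
colours, not values):

| family | dark | medium | light | neutral |
|---|---|---|---|---|
| blue | 0.05 0.15 0.55 | 0.30 0.45 0.75 | 0.62 0.72 0.90 | 0.95 0.95 0.95 |
| red | 0.60 0.08 0.08 | 0.80 0.35 0.30 | 0.92 0.65 0.60 | 0.95 0.95 0.95 |
| green | 0.05 0.40 0.12 | 0.30 0.62 0.35 | 0.65 0.85 0.65 | 0.95 0.95 0.95 |
| gray | 0.15 0.15 0.15 | 0.42 0.42 0.42 | 0.70 0.70 0.70 | 0.95 0.95 0.95 |

The continuous script interpolates linearly in RGB between neutral (0%
match) and dark (100%); every dark channel is ≤ its neutral channel, so
darkness is monotone in conservation, channel-wise. Unconserved residues stay
near-white in every family so hotspots dominate visually. `apply_offset`
shifts residue numbers for fragment models (a model of query residues
222–707 needs offset +221). Scripts are byte-stable for identical inputs.

## Synthetic data: what it emulates and what it does not

The family generator emulates a single-gene ortholog set: the query is drawn
uniformly over the 20 residues; each species' ortholog applies point
substitutions at uniformly chosen positions until the target identity is hit
(replacement residues drawn with probability ∝ exp(BLOSUM62 score / 2),
excluding the identity), then is optionally truncated or extended per a
length factor; decoys are composition-preserving shuffles of the query
re-drawn until positional identity is below 25%. The truth table records
each ortholog's realized substitution identity (within ±2 points of target
by construction). The default fixture set plants six species at 55–95%
identity with two decoys each — a realistic divergence ladder from congeneric
mammals out to fungi for a conserved globular protein — over a 150-residue
query.

Deliberately *not* emulated: insertion/deletion processes, site-rate
heterogeneity, compositional drift, paralogous families at intermediate
identity, and sequencing artefacts. Passing tests therefore demonstrate the
machinery's correctness on clean point-substitution families, not robustness
to gappy or low-complexity real data; the identity/length filters and the
exclusion workflow exist precisely because real databases violate these
idealisations.

The geometry generator builds backbones (N, CA, C, O only) from standard
peptide geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å,
ω = 180°) by sequential internal-coordinate placement: helices at φ = −57°,
ψ = −47°; hairpins as two φ = −139°, ψ = +135° strands, the second
rigid-fitted by deterministic least squares into an ideal antiparallel
hydrogen-bond register (alternating N···O pairs at 2.9 Å, CA–CA 4.9 Å),
joined by a four-residue interpolated turn. The turn is connective tissue,
not an assignment target; the idealised files are valid PDB records but are
synthetic stand-ins, not experimental structures.

## Numerical and procedural choices

- **Determinism.** No stage is stochastic; generators take explicit seeds
  and use no global random state. Registry loading, tie-breaks and output
  serialization are lexicographic; outputs carry no timestamps. Two identical
  runs produce byte-identical output directories.
- **Tie-breaks.** Equal search scores resolve by accession; equal DP cell
  values prefer diagonal, then gap-in-first, in a fixed order.
- **Degenerate inputs.** Empty species databases warn and yield no hit; an
  unloadable FASTA is skipped with a per-file note in the load report, and
  zero loadable databases is a hard error. Fewer than two sequences after
  filtering aborts the run with advice to relax thresholds. A zero-column
  alignment has no defined identity and raises.
- **Problem sizes.** Tests and the acceptance script run on 90–150-residue
  queries, 5–8 species with 1–2 decoys each, and 15–40-residue idealised
  structures — large enough for every code path (seeding, recursion, ladders)
  while keeping the whole suite under a minute.

## Known limitations

- One hit per species cannot represent duplicated same-function genes; both
  paralogs compete and only one enters the alignment.
- The progressive aligner has no iterative refinement; a pathological early
  merge is never revisited.
- Percent identity over alignment columns differs from other tools'
  conventions (e.g. identity over query length); comparisons across tools
  should re-derive identities from the alignments.
- The structure stage trusts the structure-sequence database to be in sync
  with the coordinate files beside it; mismatches surface as rejected or
  oddly mapped matches, not hard errors.
- Disordered regions: per-residue conservation is a weak instrument for
  intrinsically disordered segments, whose function often rides on coarse
  sequence features rather than conserved positions.
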