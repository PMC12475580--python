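# conservemap

Project evolutionary conservation onto a protein's 3D structure, offline.

Conserved residues that are scattered along a protein's primary sequence often
cluster into a focused "hotspot" on the folded structure's surface — a
ligand-binding site, a partner interface, a catalytic pocket. `conservemap`
semi-automates the workflow that reveals such hotspots: it finds one likely
ortholog of a query protein in each of a set of local, per-species FASTA
databases, builds an annotated multiple alignment, maps known secondary
structure onto the query from coordinate files, and writes PyMOL scripts that
paint conservation onto any 3D model of the query. It is aimed at structural
biologists who want fast, scriptable, taxonomically controlled conservation
projections without a web server.

## The method

The pipeline runs four stages:

1. **Ortholog search.** For every species database the single sequence with
   the highest gapped Smith–Waterman score against the query (BLOSUM62,
   affine gaps, gap of length *k* costing 11 + *k*) is taken as that species'
   likely ortholog. Hits are kept iff

   `lower ≤ identity% ≤ upper`  and  `100 − t ≤ 100·L_hit/L_query ≤ 100 + t`

   where identity% is identities over all alignment columns (gaps included)
   and *t* is the length-variability threshold (t = 20 keeps hits between
   80% and 120% of the query length). Defaults: lower 50, upper 100, t 20.
2. **Alignment and conservation.** Query + kept hits are aligned
   progressively (UPGMA guide tree on pairwise identity distances,
   profile–profile merges under the same scoring model). Each column gets a
   symbol — `*` invariant, `:` one strong substitution group, `.` one weak
   group, space otherwise — and each query residue gets a percent-match score
   (fraction of non-query rows matching the query there, gaps counting as
   mismatch), printed as a nine-bin Unicode bar.
3. **Structure annotation.** A structure-sequence database (FASTA with
   `ID_CHAIN` headers, coordinate files alongside) is searched for the
   query's closest modelled chain; secondary structure is assigned from the
   coordinates by Kabsch–Sander hydrogen-bond analysis
   (E = 27.888·(1/r(ON) + 1/r(CH) − 1/r(OH) − 1/r(CN)) < −0.5 kcal/mol) and
   mapped onto the query as `A` (helix) / `B` (strand) / `-` (coil) /
   `X` (not modelled). Uncovered query segments of ≥ 20 residues are
   re-searched recursively, so multi-domain proteins pick up one structure
   per domain. User-supplied models (e.g. AlphaFold predictions) go through
   the same path.
4. **Projection scripts.** Two PyMOL scripts are written: a discrete one
   colouring each residue by its conservation symbol (dark → invariant,
   neutral → unconserved) and a continuous one interpolating each residue's
   colour between the neutral and dark endpoints by its percent-match value.
   Shade families: blue (default), red, green, gray.

## Worked example

The package ships a synthetic-data generator so everything runs offline:

```sh
conservemap make-fixtures --out fx --seed 3
conservemap run --query fx/query.fasta --db-root fx/db_root \
    --struct-db fx/structures/struct_db.fasta --run-name demo
```

or equivalently `python examples/05_full_pipeline.py`, which prints:

```
output directory:
  HLX30.pdb  (9963 bytes)
  HPN20.pdb  (6723 bytes)
  demo.log  (127 bytes)
  demo_alignment.txt  (4993 bytes)
  demo_clustal.pml  (4369 bytes)
  demo_pctmatch.pml  (9647 bytes)

footer (run settings + accessions):
RUN SETTINGS
  lower identity threshold : 50 %
  upper identity threshold : 100 %
  length threshold         : 20 %
  ...
SPECIES DISPOSITIONS
  Danio rerio: kept Danio_rerio_ORTH (identity 80.5 %, length 100.0 %)
  Drosophila melanogaster: kept Drosophila_melanogaster_ORTH (identity 65.3 %, length 100.0 %)
  ...
```

The six planted orthologs (divergences 55–95%) are all recovered and pass the
default filters; the measured identities track the planted divergence of each
species. The alignment file shows the symbol and glyph lines under each
60-column block plus one `A/B/X/-` line per matched structure
(`[HLX30]`, `[HPN20]`), and the two `.pml` files replay in PyMOL to colour a
model of the query. The other `examples/*.py` scripts demonstrate each stage
on its own, printing what each number means.

## Limitations

One hit per species deliberately excludes duplicated same-function genes;
intrinsically disordered regions score poorly under per-residue conservation;
and the progressive aligner, like any, marks regions opposite a deleted
segment as unconserved — inspect the alignment and exclude problem species
(`--exclude-species`) for a re-run. See `docs/methods.md` for the full model
description, parameter table and design rationale.
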