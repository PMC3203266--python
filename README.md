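# coronin

Gene-structure-aware curation and classification of the coronin family of
actin-binding proteins.

Coronins are WD40-repeat proteins built around a conserved ~390-residue
**coronin domain** — a seven-bladed β-propeller plus a C-terminal extension
that packs against its bottom surface. Family surveys across eukaryotic
genomes face a recurring set of computational chores: genome-derived gene
models carry mispredicted exon borders that must be cross-checked against
homologs via intron positions and splice-site phases; sequences must be
binned into *Complete* / *Partial* (≤ 5% missing) / *Fragment* categories and
pseudogenes recognized by their frameshifts and in-frame stop codons;
domain architectures must be assembled (short coronins: coronin domain +
unique region + coiled-coil; tandem/class-3: two coronin domains ending in
a WASP-like CA domain; class-4: coronin domain fused to villin-derived PH,
gelsolin and villin-headpiece domains); classes must be assigned from
monophyletic grouping in the coronin-domain tree; and the oligomeric state
must be predicted from the coiled-coil **trimerization motif**

```
R1 – [ILVM]2 – X3 – X4 – [ILV]5 – E6
```

whose Arg–Glu salt bridge shields the hydrophobic positions 2 and 5.
Substitutions have characterized effects: R→K gives a concentration-
dependent trimer/tetramer equilibrium, R→A and R→Q give tetramers, a
reversed salt bridge (E…R) is still expected to trimerize, and E6→Q is
uncharacterized.

This package implements all of those steps as a tested library, plus a
seeded synthetic-family generator that emulates the family's evolutionary
scenario (metazoan class-1/class-2 duplication, ancient tandem and villin
fusions, conserved intron positions with GT..AG sites, planted curation
defects, a mutually-exclusive-exon duplication) with complete ground truth,
so every stage is verifiable without any downloads.

## Layout

- `src/coronin/` — the library:
  `seqio` (FASTA / aligned FASTA / GFF3 / Newick / annotation-TSV I/O and
  record types), `gene_structure` (intron marks and phases, splice-site
  validation, alignment projection, exon-border support flags, MXE
  detection, completeness/pseudogene rules), `motif_domain` (PSSMs, domain
  scanning, trimerization-motif rules, CA-domain search, architecture
  strings), `classification` (identity matrices, neighbor joining, clade
  assignment, sequence logos), `dataset_stats` (survey tables),
  `simulate` (the generator), `pipeline` (end-to-end drivers).
- `analysis/01…05_*.py` — numbered narrative drivers that run each stage
  and write tables under `results/`.
- `tests/` — the pytest suite, including property-based checks.

## Worked example

```
python analysis/01_simulate_family.py
python analysis/04_classify.py
```

prints (seed 42, the default study conditions):

```
wrote 52 sequences from 20 species
completeness: 43 complete, 5 partial, 3 fragments; 1 pseudogenes
...
28 reference leaves, 28 blind queries
class         class-1  class-2  class-3  class-4  unclassified
truth
class-1             5        0        0        0             0
class-2             0        5        0        0             0
class-3             0        0        7        0             0
class-4             0        0        0        3             0
unclassified        0        0        0        0             8
query recovery: 100.0%
```

Half of each class's members act as labelled reference leaves in the
coronin-domain tree; the other half are classified blind from their domain
architecture plus the smallest reference-containing clade. Non-metazoan
short coronins sit outside the class-1/class-2 duplication, so their
smallest clade mixes both classes and they correctly remain
*unclassified*. The other drivers validate splice sites and exon borders
(`02`), assemble architectures such as `CORO–U–CC`, `CORO–X–CORO–CA` and
`CORO–PH×3–GEL×5–VHP` and predict oligomeric states (`03`), and compute
conservation logos (`05`).

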