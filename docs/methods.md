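# Methods

## Coordinate and phase conventions

Genomic coordinates are 0-based half-open internally and converted to
GFF3's 1-based closed intervals only at the file boundary; protein
residues and alignment columns are 1-based. Minus-strand gene structures
are resolved once at parse time: exons are stored in transcript order and
every downstream operation sees transcript-oriented sequences.

An intron's **phase** is the number of coding nucleotides upstream of it
modulo 3 (0: between codons; 1/2: after the first/second nucleotide of a
codon). The residue attached to an intron is the interrupted codon
(phase 1/2) or the last completed codon (phase 0). This convention is
stated explicitly because gene-structure tools differ; all arithmetic in
the package and the generator uses it consistently, and it is verified in
tests against a nucleotide-walking codon enumeration.

## Annotation checking

*Splice sites.* GT..AG is canonical; GC..AG and AT..AC (the minor
spliceosome) are accepted as non-canonical; anything else is a violation
and evidence of a mispredicted border.

*Exon-border support.* Introns are projected onto the protein multiple
alignment (gaps skipped; the mapping is invertible on non-gap columns and
tested as a round trip). A border is **supported** when at least
`min_support` (default 2) other genes place an intron of the same phase
within ± `window` (default 5) alignment columns, and **suspicious**
otherwise. The defaults mirror manual curation practice — borders are
trusted when homologs agree — and are configurable. The method cannot, by
construction, flag an identical error repeated in `min_support`+ genes at
the same position; the planted-defect tests therefore use sparse,
independent shifts.

*Completeness.* `missing = (expected − observed) / expected` against the
expected full length (the family median of complete homologs, or the
generator's truth); Complete = 0, Partial ≤ 5%, Fragment otherwise. The
ratio is computed in that order so the 5% boundary is exact in floating
point.

*Pseudogenes.* Frameshifts are counted as changes in the frame deviation
along the gene: at each intron the observed phase is compared with the
family-conserved phase, and at the CDS end with frame 0; each independent
indel changes the running deviation once. Internal stop codons are
counted in the spliced translation, excluding the terminal codon. The
verdict is positive when frameshifts + stops ≥ 3 (the threshold is
configurable; "too many" is inherently a judgment call) or when at least
one lesion coincides with > 20% of the protein missing. A slid exon
border produces two deviation changes and no stops, staying below the
threshold — a curation defect, not a pseudogene.

*Mutually exclusive exons.* Consecutive internal exons are clustered when
they share an identical flanking phase context, their translated lengths
agree within 20% (relative), and the translations' ungapped identity is
≥ 0.3 (positional matches over the longer length). This covers the
structurally verifiable exon-duplication case; isoform discovery from
transcript evidence is out of scope.

## Domains and motifs

*Coronin-domain detection.* A log-odds PSSM over the 20 amino acids,
`score = log2(((count + pc·bg) / (n + pc)) / bg)` with uniform background
(1/20) and pseudocount 1.0 by default; gap and X cells are excluded from
counts, zero-count cells at pseudocount 0 are capped at −20 bits. The
scanner slides the full profile, treats X as background-neutral (0 bits),
and keeps non-overlapping windows above 0.5 bits/column greedily by
score, so a tandem coronin yields two hits. The consensus attains the
column-max upper bound exactly (tested). The 0.5 bits/column threshold
cleanly separates family members from shuffled sequences in the test
null; it is a detection proxy, not a calibrated homology search.

*Trimerization motif.* Each 6-mer in the annotated coiled-coil (or, with
no annotation, the C-terminal 60 residues) is classified as classical,
swapped (salt bridge reversed), p1-substituted (with the residue
recorded), p6-substituted, or hydrophobic-core-substituted. One motif is
reported per sequence: best class by the rank classical > swapped >
p1_sub > p6_sub > p2/p5_sub, leftmost on ties — the ranking and
tie-break are this package's choices. The oligomer rule table maps
classical and swapped to trimer; R→K to a trimer/tetramer equilibrium;
R→A and R→Q to tetramer; everything else (including the uncharacterized
E6→Q) to unknown; norleucine is not representable in sequence and falls
under the alanine rule. Coiled-coil prediction itself is out of scope:
regions come from annotations or the C-terminal window.

*CA domain.* Two small profiles (central/hydrophobic region ending in a
basic residue; acidic region) are matched independently; a CA hit
requires the acidic hit to start within `max_linker` (default 40)
residues of the central hit's end, because the linker between the two
regions varies in length. The pipeline only searches tandem candidates,
where the C-terminal CA is expected.

*Architecture strings.* Overlaps are resolved by score, then by source
priority (annotation > pssm > pattern). Runs of equal domains collapse to
`NAME×n`. A gap of ≥ 15 residues is rendered as `U` before a coiled-coil
(the short-coronin unique region) or `X` before a second coronin domain
(the tandem insertion); gaps before other domains are not named.

## Classification

Architecture is decisive where it is diagnostic: two coronin domains →
class-3; a coronin domain plus any villin-derived domain → class-4. A
single coronin domain defers to the tree: the query receives class C iff
the smallest clade containing it and any reference leaf contains
references of class C only; a mixed clade leaves it unclassified, which
is the expected outcome for non-metazoan short coronins (they predate the
class-1/class-2 duplication). Trees are rooted at a user-supplied
outgroup leaf, else at the midpoint. A tree-only class-3 call without a
tandem architecture is demoted to unclassified; a tree-supported class-4
with a bare coronin domain is accepted (such members exist). Class
variant letters (1A, 1B, …) are only propagated from reference labels,
never invented, since variant designations are not reliably orthologous.

Distance support: pairwise identity over mutually non-gap columns of a
chosen alignment region; pairs with < 10 shared columns are undefined and
excluded rather than imputed. The neighbor-joining builder is the
standard Saitou–Nei agglomeration with deterministic smallest-index
tie-breaking; it reproduces additive matrices exactly and is
cross-checked against scikit-bio's implementation. It exists for
synthetic tests and small sanity trees — large phylogenies are inputs,
not something this package infers.

*Logos.* `IC = log2 20 − H` over non-gap residue frequencies (X
excluded); letter height = frequency × IC, so heights sum to the column
IC; all-gap columns are reported as missing. The small-sample correction
(19 / (2 n ln 2)) is available but off by default so the closed forms hold
exactly.

## Dataset statistics

Pseudogenes are counted separately and excluded from completeness totals;
a `has_sequence` flag distinguishes pseudogenes without a usable protein.
The phylogeny domain count covers complete and partial non-pseudogene
sequences, with both domains of each tandem counted separately;
pseudogenes are excluded before counting (the alternative order is not
documented anywhere authoritative, so the package fixes and documents
this one). Species identity is the exact species string; no taxonomy
normalization is attempted.

## The synthetic-family generator

The generator is first-class, tested code and defines the study
conditions; all parameters live in `SimParams` with these defaults:

- 20 species, half metazoan, on a random binary species tree with branch
  lengths U(0.08, 0.25).
- An ancestral short coronin: 390-residue coronin domain (slow,
  0.12 subst/site/unit), a unique region of length drawn once from
  40–80 (fast, 0.6), and a 30–40 residue coiled-coil (0.1) carrying the
  classical motif. Sequence evolution is a per-site substitution process
  with region-specific rates — deliberately simple; no indels, no
  empirical substitution matrix.
- Class events: the short coronin duplicates into class-1/class-2 at the
  metazoan root (requesting the split elsewhere is an error); class-3
  (tandem; N-terminal domain seeded further from the ancestor than the
  C-terminal one, so the C domain groups closer to the shorts — verified
  by identity matrices) and class-4 (PH×3, GEL×5, VHP blocks, supplied to
  the pipeline as external annotations) originate at the root, with
  per-species retention of 0.6 / 0.3.
- Motif variants at tip frequencies 0.8 classical / 0.05 each
  K-, Q-substituted, swapped, E6→Q; the scanned tail is sanitized so the
  planted motif is the unique best hit, making truth recovery exact.
- Five conserved intron positions inside the coronin domain (the first
  two phase 0, enabling the MXE construction), GT..AG sites, intron
  lengths 60–120 nt, back-translation through the standard codon table
  with uniform synonymous choice.
- A mutually-exclusive exon pair is planted in ~30% of class-1 genes (at
  least 3 carriers, or none) by duplicating the exon between introns 1
  and 2 at ~88% amino-acid identity. Both copies stay in the annotated
  structure; the shared insert occupies dedicated gap columns in the
  family alignment so downstream intron projections remain comparable —
  mirroring how a curator aligns one exon of the pair.
- Defects, one category per gene (priority pseudogene > border shift >
  stop > truncation; rates 0.02 / 0.03 / 0.02 / 0.15, the last split
  60/40 into fragments of 10–35% and partials of 1–5% missing):
  a border shift slides a whole intron by +4 nt (donor and acceptor
  together, so only that border's phase changes; the absorbed
  nucleotides are resampled to avoid incidental stops, and the intron
  ends become non-splice-site); a pseudogene gets 2 frameshifts in
  distinct exons plus 1 stop; an isolated stop is placed inside the
  coronin domain. Truncations cut whole codons from the C-terminus.
  Defect proportions echo a real survey's bookkeeping (roughly 85%
  complete, ~1–3% pseudogenes).

Identical `SimParams` produce byte-identical artifacts (tested). The
emitted GFF3, genomic FASTA and protein FASTA are mutually consistent:
splicing and translating reproduces every emitted protein.

What the generator does **not** emulate — hence what passing tests do not
show about real data: alignment uncertainty (regions align by
construction), indel evolution, whole-genome duplications, EST/cDNA
evidence, sequencing-gap placement, taxonomically realistic branch
lengths, and coiled-coil prediction. Recovery rates of 100% on synthetic
families certify the bookkeeping and the rules, not the hard parts of
real curation (alignment and gene-model reconstruction, which are
explicit inputs here).

## Problem sizes

The default study family (20 species, ~50 genes, proteins up to
~1.3 kres) runs the full pipeline in well under a second; the test suite
and the acceptance script each complete in seconds, with the largest
single checks being the 10,000-sequence motif-oracle comparison and 100
neighbor-joining recoveries.
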