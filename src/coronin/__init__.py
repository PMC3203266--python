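"""Gene-structure-aware curation and classification of the coronin family.

The package covers the computational steps of a coronin-family survey:
annotation checking of gene structures (intron positions, splice-site
phases, exon-border support across homologs), domain-architecture assembly
(coronin domain, coiled-coil, CA domain, villin-derived domains),
class 1-4 assignment from architecture plus phylogenetic grouping,
oligomerization prediction from the coiled-coil trimerization motif,
mutually-exclusive-exon detection, conservation logos, and dataset
statistics.  A seeded synthetic-family generator provides ground truth for
every stage.
"""

from coronin.seqio import (
    SequenceRecord,
    AlignmentBlock,
    GeneStructure,
    read_fasta,
    write_fasta,
    read_alignment,
    write_alignment,
    read_gene_structures,
    write_gene_structures,
    read_tree,
    write_tree,
    read_domain_annotations,
)

__version__ = "0.1.0"

__all__ = [
    "SequenceRecord",
    "AlignmentBlock",
    "GeneStructure",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_gene_structures",
    "write_gene_structures",
    "read_tree",
    "write_tree",
    "read_domain_annotations",
]
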