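"""Core record types and readers/writers for the pipeline's file formats.

Formats handled: FASTA (protein and genomic), aligned FASTA, GFF3 gene
structures (CDS features only), Newick trees, and a TSV dialect for
external domain annotations.

Coordinate conventions
----------------------
Genomic coordinates are 0-based half-open internally and converted to/from
GFF3's 1-based closed intervals at the file boundary.  Protein residues are
1-based throughout.  Minus-strand gene structures are resolved once at
parse time: exons are stored in transcript (5'->3') order and all spliced
sequences are returned in transcript orientation.

FASTA headers may carry metadata in the pipeline's ``id|species|class``
dialect; plain headers remain valid with the metadata absent.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

AA20 = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AA20 + "X")

CLASS_LABELS_BASE = ("class-1", "class-2", "class-3", "class-4", "unclassified")

_CLASS_RE = re.compile(r"^(class-[12][A-Z]?|class-[34]|unclassified)$")


class SeqIOError(ValueError):
    """Raised for malformed sequence, alignment, tree or annotation input."""


def _check_class_label(label: Optional[str]) -> Optional[str]:
    if label is None or label == "":
        return None
    if not _CLASS_RE.match(label):
        raise SeqIOError(f"invalid class label {label!r}")
    return label


@dataclass
class SequenceRecord:
    """A protein sequence with its curation metadata.

    ``completeness`` is one of Complete/Partial/Fragment once assigned;
    ``has_sequence`` distinguishes pseudogenes for which no usable protein
    could be derived (they are still counted).
    """

    id: str
    protein: str
    species: str = ""
    class_label: Optional[str] = None
    completeness: Optional[str] = None
    pseudogene: Optional[bool] = None
    from_wgs: Optional[bool] = None
    has_sequence: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("empty sequence id")
        if not self.protein:
            raise SeqIOError(f"{self.id}: empty protein sequence")
        for pos, aa in enumerate(self.protein, start=1):
            if aa not in VALID_RESIDUES:
                raise SeqIOError(
                    f"{self.id}: illegal residue {aa!r} at position {pos}"
                )
        self.class_label = _check_class_label(self.class_label)
        if self.completeness not in (None, "Complete", "Partial", "Fragment"):
            raise SeqIOError(
                f"{self.id}: invalid completeness {self.completeness!r}"
            )

    def __len__(self) -> int:
        return len(self.protein)


@dataclass
class AlignmentBlock:
    """A protein multiple alignment: equal-length gapped rows."""

    rows: list[tuple[str, str]]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise SeqIOError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            detail = ", ".join(f"{i}:{len(s)}" for i, s in self.rows)
            raise SeqIOError(f"ragged alignment rows ({detail})")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise SeqIOError("duplicate row id in alignment")
        self.length = lengths.pop()
        self._index = {i: k for k, (i, _) in enumerate(self.rows)}

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, row_id: str) -> str:
        return self.rows[self._index[row_id]][1]

    def __contains__(self, row_id: str) -> bool:
        return row_id in self._index

    @staticmethod
    def degap(row: str) -> str:
        return row.replace("-", "").replace(".", "")

    def all_gap_rows(self) -> list[str]:
        """Row ids consisting only of gaps (accepted, but worth flagging)."""
        return [i for i, s in self.rows if not self.degap(s)]


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneStructure:
    """Ordered coding exons on a genomic locus.

    ``exons`` are 0-based half-open intervals on ``genomic`` listed in
    transcript (5'->3') order: ascending genomic coordinates on '+',
    descending on '-'.  Intron lengths must be >= 4 nt.  A total CDS length
    not divisible by 3 is allowed (truncations, pseudogenes) but flagged
    via :attr:`in_frame`.
    """

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    genomic: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SeqIOError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise SeqIOError(f"{self.gene_id}: no exons")
        glen = len(self.genomic)
        for s, e in self.exons:
            if not (0 <= s < e <= glen):
                raise SeqIOError(
                    f"{self.gene_id}: exon ({s},{e}) outside genomic "
                    f"sequence of length {glen}"
                )
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise SeqIOError(
                    f"{self.gene_id}: overlapping exons ({s1},{e1}) and "
                    f"({s2},{e2})"
                )
        expected = ordered if self.strand == "+" else ordered[::-1]
        if self.exons != expected:
            raise SeqIOError(
                f"{self.gene_id}: exons not in transcript order for "
                f"strand {self.strand}"
            )
        for i in range(len(self.exons) - 1):
            if self.intron_length(i) < 4:
                raise SeqIOError(
                    f"{self.gene_id}: intron {i + 1} shorter than 4 nt"
                )

    # -- derived views (all transcript-oriented) --

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_seq(self, i: int) -> str:
        s, e = self.exons[i]
        seq = self.genomic[s:e]
        return seq if self.strand == "+" else revcomp(seq)

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    def _intron_interval(self, i: int) -> tuple[int, int]:
        """Genomic interval of intron i (0-based), orientation-agnostic."""
        if self.strand == "+":
            return self.exons[i][1], self.exons[i + 1][0]
        return self.exons[i + 1][1], self.exons[i][0]

    def intron_length(self, i: int) -> int:
        s, e = self._intron_interval(i)
        return e - s

    def intron_seq(self, i: int) -> str:
        s, e = self._intron_interval(i)
        seq = self.genomic[s:e]
        return seq if self.strand == "+" else revcomp(seq)

    @property
    def cds(self) -> str:
        return "".join(self.exon_seq(i) for i in range(len(self.exons)))

    @property
    def in_frame(self) -> bool:
        return len(self.cds) % 3 == 0

    def translate(self) -> str:
        """Translate the spliced CDS (trailing partial codon dropped,
        terminal stop stripped); internal stops appear as '*'."""
        cds = self.cds
        cds = cds[: len(cds) - len(cds) % 3]
        prot = str(Seq(cds).translate())
        if prot.endswith("*"):
            prot = prot[:-1]
        return prot


# ---------------------------------------------------------------------------
# FASTA


def _parse_header(header: str) -> tuple[str, str, Optional[str]]:
    parts = header.split("|")
    seq_id = parts[0]
    species = parts[1] if len(parts) > 1 else ""
    class_label = parts[2] if len(parts) > 2 and parts[2] else None
    return seq_id, species, class_label


def read_fasta(path) -> list[SequenceRecord]:
    """Read protein FASTA into :class:`SequenceRecord` objects, file order
    preserved.  Header metadata follows the ``id|species|class`` dialect.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, species, class_label = _parse_header(rec.id)
        if seq_id in seen:
            raise SeqIOError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        records.append(
            SequenceRecord(
                id=seq_id,
                protein=str(rec.seq).upper(),
                species=species,
                class_label=class_label,
            )
        )
    return records


def _format_fasta(header: str, seq: str, width: int = 60) -> str:
    lines = [f">{header}"]
    for i in range(0, len(seq), width):
        lines.append(seq[i : i + width])
    return "\n".join(lines) + "\n"


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.species or rec.class_label:
                header = f"{rec.id}|{rec.species}|{rec.class_label or ''}"
            fh.write(_format_fasta(header, rec.protein))


def read_genomic_fasta(path) -> dict[str, str]:
    """Plain nucleotide FASTA as an id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SeqIOError(f"duplicate genomic sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_genomic_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(_format_fasta(name, seq))


# ---------------------------------------------------------------------------
# Aligned FASTA


def read_alignment(path) -> AlignmentBlock:
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return AlignmentBlock(rows)


def write_alignment(aln: AlignmentBlock, path) -> None:
    with open(path, "w") as fh:
        for row_id, row in aln.rows:
            fh.write(_format_fasta(row_id, row))


# ---------------------------------------------------------------------------
# GFF3 gene structures (CDS features only)


def read_gene_structures(gff_path, genomic: dict[str, str]) -> list[GeneStructure]:
    """Parse GFF3 CDS lines grouped by ``Parent`` into gene structures.

    ``genomic`` maps seqid -> nucleotide sequence.  Coordinates are
    converted from 1-based closed to 0-based half-open; minus-strand exon
    lists are reordered into transcript orientation.
    """
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise SeqIOError(f"{gff_path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            parent = attr.get("Parent") or attr.get("ID")
            if parent is None:
                raise SeqIOError(f"{gff_path}:{lineno}: CDS without Parent/ID")
            g = groups.setdefault(parent, {"seqid": seqid, "strand": strand, "exons": []})
            if g["seqid"] != seqid or g["strand"] != strand:
                raise SeqIOError(f"{parent}: CDS features on mixed seqid/strand")
            g["exons"].append((int(start) - 1, int(end)))
            if parent not in order:
                order.append(parent)
    structures = []
    for gene_id in order:
        g = groups[gene_id]
        if g["seqid"] not in genomic:
            raise SeqIOError(f"{gene_id}: unknown genomic sequence {g['seqid']!r}")
        exons = sorted(g["exons"])
        if g["strand"] == "-":
            exons = exons[::-1]
        structures.append(
            GeneStructure(
                gene_id=gene_id,
                strand=g["strand"],
                exons=exons,
                genomic=genomic[g["seqid"]],
            )
        )
    return structures


def write_gene_structures(
    structures: Sequence[GeneStructure], path, seqids: Optional[dict[str, str]] = None
) -> None:
    """Write CDS features in canonical GFF3 (one locus per gene by default)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gs in structures:
            seqid = (seqids or {}).get(gs.gene_id, gs.gene_id + "_locus")
            exons = sorted(gs.exons)
            for s, e in exons:
                fh.write(
                    f"{seqid}\tcoronin\tCDS\t{s + 1}\t{e}\t.\t{gs.strand}\t.\t"
                    f"Parent={gs.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Newick trees


def read_tree(path_or_str) -> dendropy.Tree:
    """Read a Newick tree; polytomies are preserved."""
    data = str(path_or_str)
    try:
        if "(" in data and ";" in data:
            tree = dendropy.Tree.get(
                data=data, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=data, schema="newick", preserve_underscores=True
            )
    except Exception as exc:  # dendropy raises several parse error types
        raise SeqIOError(f"newick parse failure: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise SeqIOError("duplicate leaf names in tree")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Domain annotation TSV


ANNOTATION_COLUMNS = ["seq_id", "domain_name", "start", "end", "source"]


def read_domain_annotations(path) -> pd.DataFrame:
    """Tabular external domain annotations (PH, gelsolin, VHP, CC, ...).

    Columns: seq_id, domain_name, start, end (1-based inclusive residues),
    source.
    """
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "domain_name": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SeqIOError(f"annotation TSV missing columns: {missing}")
    if ((df["start"] < 1) | (df["end"] < df["start"])).any():
        raise SeqIOError("annotation TSV contains invalid start/end coordinates")
    return df[ANNOTATION_COLUMNS]


def write_domain_annotations(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)
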