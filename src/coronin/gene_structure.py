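"""Intron-level annotation checking of coronin gene structures.

The operations here implement the curation logic used when validating
gene-family annotations against each other: computing intron positions and
splice-site phases, confirming canonical donor/acceptor dinucleotides,
projecting introns onto a protein multiple alignment, flagging exon
borders that lack support from homologous genes, detecting clusters of
mutually exclusive (duplicated) exons, and applying the completeness and
pseudogene rules.

Phase convention: ``phase = (coding nucleotides upstream of the intron)
mod 3``, i.e. phase 0 introns fall between codons, phase 1/2 introns
interrupt a codon after its first/second nucleotide.  The residue
associated with an intron is the interrupted codon (phase 1/2) or the last
completed codon (phase 0), 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from coronin.seqio import AlignmentBlock, GeneStructure, SequenceRecord

DEFAULT_MIN_SUPPORT = 2
DEFAULT_WINDOW = 5
DEFAULT_LESION_THRESHOLD = 3

PARTIAL_MAX_MISSING = 0.05
FRAGMENT_MISSING_FOR_LESION = 0.2


@dataclass(frozen=True)
class IntronMark:
    """An intron's position on the protein, optionally lifted onto an
    alignment column."""

    gene_id: str
    intron_index: int  # 1-based, 5'->3'
    cds_nt_before: int
    residue: int  # 1-based
    phase: int  # 0, 1, 2
    column: Optional[int] = None  # 1-based alignment column

    def __post_init__(self) -> None:
        assert self.phase == self.cds_nt_before % 3
        expected = (
            self.cds_nt_before // 3
            if self.phase == 0
            else self.cds_nt_before // 3 + 1
        )
        assert self.residue == expected


@dataclass(frozen=True)
class SpliceCheck:
    gene_id: str
    intron_index: int
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    status: str  # canonical | noncanonical | violation


@dataclass(frozen=True)
class BorderFlag:
    gene_id: str
    intron_index: int
    column: int
    n_support: int
    verdict: str  # supported | suspicious


@dataclass(frozen=True)
class MxeCluster:
    gene_id: str
    exon_indices: tuple[int, ...]  # 1-based, consecutive internal exons
    pairwise_identity: float
    phase_context: tuple[int, int]


@dataclass(frozen=True)
class CompletenessCall:
    seq_id: str
    missing_fraction: float
    category: str  # Complete | Partial | Fragment


@dataclass(frozen=True)
class PseudogeneCall:
    seq_id: str
    n_frameshifts: int
    n_internal_stops: int
    missing_fraction: float
    verdict: bool


# ---------------------------------------------------------------------------


def intron_marks(gs: GeneStructure) -> list[IntronMark]:
    """One mark per intron, 5'->3'; a single-exon gene yields []."""
    marks = []
    cum = 0
    lengths = gs.exon_lengths()
    for i in range(gs.n_introns):
        cum += lengths[i]
        phase = cum % 3
        residue = cum // 3 if phase == 0 else cum // 3 + 1
        marks.append(
            IntronMark(
                gene_id=gs.gene_id,
                intron_index=i + 1,
                cds_nt_before=cum,
                residue=residue,
                phase=phase,
            )
        )
    return marks


_CANONICAL = {("GT", "AG")}
_NONCANONICAL = {("GC", "AG"), ("AT", "AC")}


def validate_splice_sites(gs: GeneStructure) -> list[SpliceCheck]:
    """Classify each intron's donor/acceptor dinucleotides.

    GT..AG is the consensus (canonical); GC..AG and AT..AC are the known
    minor spliceosomal variants (noncanonical); anything else is a
    violation, i.e. evidence of a mispredicted exon border.
    """
    checks = []
    for i in range(gs.n_introns):
        intron = gs.intron_seq(i)
        donor, acceptor = intron[:2], intron[-2:]
        pair = (donor, acceptor)
        if pair in _CANONICAL:
            status = "canonical"
        elif pair in _NONCANONICAL:
            status = "noncanonical"
        else:
            status = "violation"
        checks.append(
            SpliceCheck(
                gene_id=gs.gene_id,
                intron_index=i + 1,
                donor_dinucleotide=donor,
                acceptor_dinucleotide=acceptor,
                status=status,
            )
        )
    return checks


def residue_to_column(row: str, residue: int) -> int:
    """Alignment column (1-based) of the residue-th non-gap character."""
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch not in "-.":
            count += 1
            if count == residue:
                return col
    raise ValueError(f"residue {residue} beyond ungapped row length {count}")


def column_to_residue(row: str, column: int) -> Optional[int]:
    """Inverse of :func:`residue_to_column` on non-gap columns."""
    if row[column - 1] in "-.":
        return None
    return sum(1 for ch in row[:column] if ch not in "-.")


def project_introns(
    aln: AlignmentBlock,
    marks: Sequence[IntronMark],
    id_map: Optional[dict[str, str]] = None,
) -> list[IntronMark]:
    """Fill each mark's alignment column via its gene's alignment row.

    ``id_map`` maps gene_id -> alignment row id when they differ.
    """
    projected = []
    for mark in marks:
        row_id = (id_map or {}).get(mark.gene_id, mark.gene_id)
        if row_id not in aln:
            raise KeyError(f"no alignment row for gene {mark.gene_id!r}")
        row = aln.row(row_id)
        try:
            col = residue_to_column(row, mark.residue)
        except ValueError as exc:
            raise ValueError(f"{mark.gene_id} intron {mark.intron_index}: {exc}")
        projected.append(replace(mark, column=col))
    return projected


def flag_borders(
    projected_marks: Sequence[IntronMark],
    min_support: int = DEFAULT_MIN_SUPPORT,
    window: int = DEFAULT_WINDOW,
) -> list[BorderFlag]:
    """Flag introns not shared (same phase, column within +-window) by at
    least ``min_support`` other genes.

    Support counts distinct other genes, mirroring the manual practice of
    trusting an exon border only when homologous genes place an intron of
    the same phase at the same alignment position.
    """
    if any(m.column is None for m in projected_marks):
        raise ValueError("marks must be projected (column set) before flagging")
    flags = []
    for mark in projected_marks:
        supporters = {
            m.gene_id
            for m in projected_marks
            if m.gene_id != mark.gene_id
            and m.phase == mark.phase
            and abs(m.column - mark.column) <= window
        }
        n = len(supporters)
        flags.append(
            BorderFlag(
                gene_id=mark.gene_id,
                intron_index=mark.intron_index,
                column=mark.column,
                n_support=n,
                verdict="supported" if n >= min_support else "suspicious",
            )
        )
    return flags


# ---------------------------------------------------------------------------
# Mutually exclusive exons

from Bio.Seq import Seq  # noqa: E402


def _exon_translation(gs: GeneStructure, exon_idx: int, upstream_phase: int) -> str:
    """Translate exon ``exon_idx`` (0-based) in its reading frame, skipping
    the partial codon completed by the upstream exon."""
    seq = gs.exon_seq(exon_idx)
    offset = (3 - upstream_phase) % 3
    seq = seq[offset:]
    seq = seq[: len(seq) - len(seq) % 3]
    return str(Seq(seq).translate()) if seq else ""


def _ungapped_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def detect_mxe(
    gs: GeneStructure,
    min_identity: float = 0.3,
    len_tol: float = 0.2,
) -> list[MxeCluster]:
    """Detect clusters of candidate mutually exclusive exons.

    Consecutive internal exons are clustered when they share an identical
    flanking phase context (upstream and downstream intron phases), their
    translated lengths agree within ``len_tol`` (relative), and the
    ungapped pairwise identity of the translations is >= ``min_identity``.
    A duplicated internal exon retained in the annotation therefore shows
    up as a 2-exon cluster.
    """
    n = len(gs.exons)
    if n < 3:
        return []
    phases = [m.phase for m in intron_marks(gs)]

    def context(k: int) -> tuple[int, int]:
        # k is a 0-based internal exon index (1 .. n-2)
        return (phases[k - 1], phases[k])

    def compatible(k: int, j: int) -> bool:
        if context(k) != context(j):
            return False
        ta = _exon_translation(gs, k, phases[k - 1])
        tb = _exon_translation(gs, j, phases[j - 1])
        if not ta or not tb:
            return False
        if abs(len(ta) - len(tb)) / max(len(ta), len(tb)) > len_tol:
            return False
        return _ungapped_identity(ta, tb) >= min_identity

    clusters = []
    k = 1
    while k < n - 2:
        if compatible(k, k + 1):
            members = [k, k + 1]
            while members[-1] + 1 < n - 1 and compatible(members[-1], members[-1] + 1):
                members.append(members[-1] + 1)
            idents = [
                _ungapped_identity(
                    _exon_translation(gs, a, phases[a - 1]),
                    _exon_translation(gs, b, phases[b - 1]),
                )
                for ai, a in enumerate(members)
                for b in members[ai + 1 :]
            ]
            clusters.append(
                MxeCluster(
                    gene_id=gs.gene_id,
                    exon_indices=tuple(m + 1 for m in members),
                    pairwise_identity=min(idents),
                    phase_context=context(members[0]),
                )
            )
            k = members[-1] + 1
        else:
            k += 1
    return clusters


# ---------------------------------------------------------------------------
# Completeness and pseudogene rules


def call_completeness(seq: SequenceRecord, expected_length: int) -> CompletenessCall:
    """Categorize a sequence by the fraction of the expected protein that
    is missing: Complete (0), Partial (<= 5%), Fragment (more)."""
    if expected_length <= 0:
        raise ValueError("expected_length must be positive")
    # (expected - observed) / expected keeps the 5% boundary exact in floats
    missing = max(0.0, (expected_length - len(seq.protein)) / expected_length)
    if missing == 0.0:
        category = "Complete"
    elif missing <= PARTIAL_MAX_MISSING:
        category = "Partial"
    else:
        category = "Fragment"
    return CompletenessCall(seq_id=seq.id, missing_fraction=missing, category=category)


def call_pseudogene(
    gs: GeneStructure,
    expected_phases: Optional[Sequence[int]] = None,
    missing_fraction: float = 0.0,
    lesion_threshold: int = DEFAULT_LESION_THRESHOLD,
) -> PseudogeneCall:
    """Count coding lesions and apply the pseudogene rule.

    Frameshifts are counted as changes in the frame deviation across exon
    borders: at each intron the observed phase is compared with the
    conserved family phase (``expected_phases``), and at the gene end the
    total CDS length is compared with frame 0.  Each independent indel
    changes the running deviation once.  Without ``expected_phases`` only
    the terminal frame test is available.  Internal stops are counted in
    the spliced translation, excluding the terminal codon.

    Verdict: true iff frameshifts + stops >= ``lesion_threshold``, or at
    least one lesion coincides with > 20% of the protein missing — more
    damage than sequencing or assembly errors explain.
    """
    marks = intron_marks(gs)
    cds_len = len(gs.cds)
    deviations: list[int] = []
    if expected_phases is not None:
        if len(expected_phases) != len(marks):
            raise ValueError(
                f"{gs.gene_id}: expected {len(marks)} phases, "
                f"got {len(expected_phases)}"
            )
        deviations = [
            (m.phase - exp) % 3 for m, exp in zip(marks, expected_phases)
        ]
    deviations.append(cds_len % 3)
    n_frameshifts = 0
    prev = 0
    for dev in deviations:
        if dev != prev:
            n_frameshifts += 1
            prev = dev
    translation = gs.translate()
    n_internal_stops = translation[:-1].count("*") if translation else 0
    lesions = n_frameshifts + n_internal_stops
    verdict = lesions >= lesion_threshold or (
        lesions >= 1 and missing_fraction > FRAGMENT_MISSING_FOR_LESION
    )
    return PseudogeneCall(
        seq_id=gs.gene_id,
        n_frameshifts=n_frameshifts,
        n_internal_stops=n_internal_stops,
        missing_fraction=missing_fraction,
        verdict=verdict,
    )
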