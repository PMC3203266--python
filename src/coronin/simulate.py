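"""Seeded generator of coronin-like gene families with full ground truth.

The generator emulates the evolutionary scenario behind the family's four
classes: an ancestral short coronin (a ~390-residue coronin domain, a
fast-evolving unique region, and a C-terminal coiled-coil carrying the
trimerization motif) evolves along a eukaryote-like species tree; a gene
duplication at the metazoan root yields class-1 and class-2; a tandem
duplication plus fusion at the family root yields class-3 (two coronin
domains, the C-terminal one closer to the short-coronin ancestor, ending
in a CA domain and lacking a coiled-coil); a fusion with villin-derived
domains yields class-4 (PH, gelsolin and villin-headpiece blocks, supplied
downstream as external annotations).  Most lineages lose class-3/class-4,
controlled by presence fractions.

Genes are back-translated with a fixed codon table, receive introns at
family-conserved positions and phases with canonical GT..AG sites, and can
be corrupted with curation-style defects: slid exon borders, frameshifts,
in-frame stop codons and truncations.  A cluster of mutually exclusive
exons (a duplicated internal exon with matching flanking phases) can be
planted in class-1 genes.  Everything is derived from a single seed;
identical parameters produce byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from coronin.seqio import (
    AA20,
    AlignmentBlock,
    GeneStructure,
    SequenceRecord,
    revcomp,
    write_alignment,
    write_domain_annotations,
    write_fasta,
    write_gene_structures,
    write_genomic_fasta,
)
from coronin.motif_domain import classify_motif_window

AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

# per-region substitution rates (expected substitutions per site per unit
# branch length): the coronin domain is slow, unique regions fast
REGION_RATES = {
    "CORO": 0.12,
    "U": 0.6,
    "CC": 0.1,
    "X": 0.5,
    "CA_C": 0.08,
    "CA_L": 0.5,
    "CA_A": 0.1,
    "PH": 0.1,
    "GEL": 0.1,
    "VHP": 0.1,
    "GAP": 0.5,
}

MOTIF_OFFSET_IN_CC = 10  # 0-based offset of the motif within the coiled-coil

#: intended oligomeric state of each plantable motif variant
VARIANT_STATES = {
    "classical": "trimer",
    "swapped": "trimer",
    "p1_K": "trimer_tetramer_equilibrium",
    "p1_A": "tetramer",
    "p1_Q": "tetramer",
    "p6_Q": "unknown",
}

_VARIANT_EDITS = {
    "classical": {},
    "swapped": {1: "E", 6: "R"},
    "p1_K": {1: "K"},
    "p1_A": {1: "A"},
    "p1_Q": {1: "Q"},
    "p6_Q": {6: "Q"},
}

_VARIANT_CALL = {  # what classify_motif_window reports for each planting
    "classical": "classical",
    "swapped": "swapped",
    "p1_K": "p1_sub(K)",
    "p1_A": "p1_sub(A)",
    "p1_Q": "p1_sub(Q)",
    "p6_Q": "p6_sub(Q)",
}


@dataclass
class ClassEventSpec:
    """Which lineages receive which class-defining events."""

    split_lineage: str = "metazoa"  # class-1/class-2 duplication point
    class3_fraction: float = 0.6  # fraction of species retaining class-3
    class4_fraction: float = 0.3  # fraction retaining class-4

    def __post_init__(self) -> None:
        if self.split_lineage != "metazoa":
            raise ValueError(
                "the class-1/class-2 duplication is metazoan-specific; "
                f"got split_lineage={self.split_lineage!r}"
            )


@dataclass
class IntronModel:
    n_introns: int = 5
    canonical_site_prob: float = 1.0
    intron_length_range: tuple[int, int] = (60, 120)


@dataclass
class ErrorModel:
    """Per-gene defect probabilities.

    Defect categories are mutually exclusive per gene (priority order:
    pseudogene, border shift, stop, frameshift, truncation), so each
    corrupted gene carries a single, cleanly attributable defect.
    ``pseudogene_rate`` plants ``n_frameshifts`` frameshifts plus
    ``n_stops`` stop codons together (a disabled gene); ``stop_rate`` and
    ``frameshift_rate`` plant isolated lesions below the pseudogene
    threshold.
    """

    border_shift_rate: float = 0.0
    frameshift_rate: float = 0.0
    stop_rate: float = 0.0
    truncation_rate: float = 0.0
    pseudogene_rate: float = 0.0
    n_frameshifts: int = 2
    n_stops: int = 1
    border_shift_nt: int = 4
    partial_fraction_range: tuple[float, float] = (0.01, 0.05)
    fragment_fraction_range: tuple[float, float] = (0.1, 0.35)
    fragment_prob_given_truncation: float = 0.6

    def __post_init__(self) -> None:
        for name in (
            "border_shift_rate",
            "frameshift_rate",
            "stop_rate",
            "truncation_rate",
            "pseudogene_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SimParams:
    seed: int = 42
    n_species: int = 20
    metazoan_fraction: float = 0.5
    class_events: ClassEventSpec = field(default_factory=ClassEventSpec)
    coro_length: int = 390
    cc_length_range: tuple[int, int] = (30, 40)
    unique_length_range: tuple[int, int] = (40, 80)
    motif_variant_frequencies: dict = field(
        default_factory=lambda: {
            "classical": 0.8,
            "p1_K": 0.05,
            "p1_Q": 0.05,
            "swapped": 0.05,
            "p6_Q": 0.05,
        }
    )
    intron_model: IntronModel = field(default_factory=IntronModel)
    error_model: ErrorModel = field(
        default_factory=lambda: ErrorModel(
            border_shift_rate=0.03,
            stop_rate=0.02,
            truncation_rate=0.15,
            pseudogene_rate=0.02,
        )
    )
    mxe_fraction: float = 0.3  # fraction of class-1 genes with a planted MXE pair
    mxe_identity: float = 0.88  # target amino-acid identity of the exon copy

    def __post_init__(self) -> None:
        freqs = self.motif_variant_frequencies
        unknown = set(freqs) - set(_VARIANT_EDITS)
        if unknown:
            raise ValueError(f"unknown motif variants: {sorted(unknown)}")
        total = sum(freqs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"motif variant frequencies sum to {total}, not 1")
        if not 0.0 <= self.metazoan_fraction <= 1.0:
            raise ValueError("metazoan_fraction must be in [0,1]")


# ---------------------------------------------------------------------------
# small sequence helpers (integer-coded proteins)


def _random_protein(rng: np.random.Generator, length: int, alphabet: str = AA20) -> np.ndarray:
    idx = rng.integers(0, len(alphabet), size=length)
    return np.array([AA_INDEX[alphabet[i]] for i in idx], dtype=np.int8)


def _biased_protein(rng: np.random.Generator, length: int, letters: str) -> np.ndarray:
    """Random protein drawn 70/30 from a biased alphabet vs all 20."""
    out = np.empty(length, dtype=np.int8)
    for i in range(length):
        pool = letters if rng.random() < 0.7 else AA20
        out[i] = AA_INDEX[pool[rng.integers(0, len(pool))]]
    return out


def _evolve(arr: np.ndarray, rate: float, branch_length: float, rng: np.random.Generator) -> np.ndarray:
    p = 1.0 - np.exp(-rate * branch_length)
    mask = rng.random(arr.size) < p
    out = arr.copy()
    if mask.any():
        shift = rng.integers(1, 20, size=int(mask.sum()))
        out[mask] = (out[mask] + shift) % 20
    return out


def _to_str(arr: np.ndarray) -> str:
    return "".join(AA20[i] for i in arr)


# ---------------------------------------------------------------------------
# species tree


@dataclass
class _SpNode:
    length: float
    name: Optional[str] = None
    children: list = field(default_factory=list)
    is_metazoan_root: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _random_clade(names: list[str], rng: np.random.Generator, stem: float) -> _SpNode:
    if len(names) == 1:
        return _SpNode(length=stem, name=names[0])
    k = int(rng.integers(1, len(names)))
    left = _random_clade(names[:k], rng, float(rng.uniform(0.08, 0.25)))
    right = _random_clade(names[k:], rng, float(rng.uniform(0.08, 0.25)))
    return _SpNode(length=stem, children=[left, right])


def _species_tree(params: SimParams, rng: np.random.Generator) -> tuple[_SpNode, list[str], list[str]]:
    n_met = int(round(params.metazoan_fraction * params.n_species))
    n_met = min(max(n_met, 0), params.n_species)
    if 0 < n_met < 2:
        n_met = 2
    if n_met > params.n_species - 1:
        n_met = params.n_species - 1
    metazoans = [f"Met{i + 1:02d}" for i in range(n_met)]
    others = [f"Non{i + 1:02d}" for i in range(params.n_species - n_met)]
    met_order = list(rng.permutation(metazoans))
    non_order = list(rng.permutation(others))
    met_clade = _random_clade(met_order, rng, stem=0.15)
    met_clade.is_metazoan_root = True
    non_clade = _random_clade(non_order, rng, stem=0.15)
    root = _SpNode(length=0.0, children=[non_clade, met_clade])
    return root, metazoans, others


def _newick(node: _SpNode, rename=None) -> str:
    def rec(n: _SpNode) -> str:
        if n.is_leaf:
            label = rename(n.name) if rename else n.name
            return f"{label}:{n.length:.5f}"
        inner = ",".join(rec(c) for c in n.children)
        return f"({inner}):{n.length:.5f}"

    if node.is_leaf:
        return rec(node) + ";"
    inner = ",".join(rec(c) for c in node.children)
    return f"({inner});"


def _induced_newick(node: _SpNode, mapper) -> Optional[tuple[str, float]]:
    """Newick of the subtree induced by leaves for which mapper(name) is a
    label; unary nodes collapse with added branch lengths."""
    if node.is_leaf:
        label = mapper(node.name)
        if label is None:
            return None
        return f"{label}", node.length
    kids = [r for r in (_induced_newick(c, mapper) for c in node.children) if r]
    if not kids:
        return None
    if len(kids) == 1:
        s, ln = kids[0]
        return s, ln + node.length
    inner = ",".join(f"{s}:{ln:.5f}" for s, ln in kids)
    return f"({inner})", node.length


# ---------------------------------------------------------------------------
# gene models


@dataclass
class _Region:
    name: str
    seq: np.ndarray  # int8-coded residues


@dataclass
class _GeneModel:
    regions: list[_Region]

    def copy(self) -> "_GeneModel":
        return _GeneModel([_Region(r.name, r.seq.copy()) for r in self.regions])

    def evolve(self, bl: float, rng: np.random.Generator) -> "_GeneModel":
        return _GeneModel(
            [
                _Region(r.name, _evolve(r.seq, REGION_RATES[r.name], bl, rng))
                for r in self.regions
            ]
        )

    def protein(self) -> str:
        return "".join(_to_str(r.seq) for r in self.regions)

    def coords(self) -> dict[str, list[tuple[int, int]]]:
        """1-based inclusive coordinates of every region occurrence."""
        out: dict[str, list[tuple[int, int]]] = {}
        pos = 0
        for r in self.regions:
            out.setdefault(r.name, []).append((pos + 1, pos + len(r.seq)))
            pos += len(r.seq)
        return out


# ---------------------------------------------------------------------------
# motif planting


def mutate_motif(motif_window: str, substitution: dict[int, str]) -> str:
    """Apply position (1-6) -> residue edits to a 6-residue motif window."""
    if len(motif_window) != 6:
        raise ValueError("motif window must be 6 residues")
    chars = list(motif_window)
    for pos, aa in substitution.items():
        if not 1 <= pos <= 6:
            raise ValueError(f"invalid motif position {pos}")
        if aa not in AA20:
            raise ValueError(f"invalid residue {aa!r}")
        chars[pos - 1] = aa
    return "".join(chars)


def _plant_motif(
    protein: list[str],
    motif_start0: int,
    variant: str,
    tail_start0: int,
    rng: np.random.Generator,
) -> None:
    """Overwrite the motif window in place and neutralize accidental motif
    windows in the scanned tail so the planted motif is the unique best."""
    template = mutate_motif("RLKSVE", _VARIANT_EDITS[variant])
    # keep the evolved X positions (3, 4) for realism
    window = list(template)
    window[2] = protein[motif_start0 + 2]
    window[3] = protein[motif_start0 + 3]
    protein[motif_start0 : motif_start0 + 6] = window
    for _ in range(20):
        dirty = False
        for s in range(tail_start0, len(protein) - 5):
            if s == motif_start0:
                continue
            if abs(s - motif_start0) < 6:
                continue  # overlapping windows cannot outrank the planted one
            if classify_motif_window("".join(protein[s : s + 6])) is not None:
                protein[s + 1] = "G"  # break the hydrophobic position 2
                if protein[s] in "RE":
                    protein[s] = "S"  # and the salt bridge
                dirty = True
        if not dirty:
            break


# ---------------------------------------------------------------------------
# back-translation and gene structure materialization

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)

_STOPS = {"TAA", "TAG", "TGA"}


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS[aa]
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _translate_cds(cds: str) -> str:
    from Bio.Seq import Seq

    cds = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def _conserved_intron_positions(
    params: SimParams, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Family-conserved intron sites: (cds_nt_before list, phase list).

    The first two introns get phase 0 so the exon between them can host a
    mutually-exclusive duplication.
    """
    n = params.intron_model.n_introns
    lo, hi = 15, params.coro_length - 15
    while True:
        residues = np.sort(rng.choice(np.arange(lo, hi), size=n, replace=False))
        if n < 2 or np.diff(residues).min() >= 20:
            break
    phases = [0, 0] + [int(p) for p in rng.integers(0, 3, size=max(0, n - 2))]
    phases = phases[:n]
    positions = []
    for r, p in zip(residues, phases):
        c = 3 * int(r) if p == 0 else 3 * (int(r) - 1) + p
        positions.append(c)
    return positions, phases


def _marks_from_positions(positions: list[int]) -> list[tuple[int, int, int]]:
    out = []
    for c in positions:
        phase = c % 3
        residue = c // 3 if phase == 0 else c // 3 + 1
        out.append((c, residue, phase))
    return out


def _materialize(
    gene_id: str,
    cds: str,
    positions: list[int],
    rng: np.random.Generator,
    intron_model: IntronModel,
    violated_intron: Optional[int] = None,
    flank: int = 50,
) -> tuple[GeneStructure, str]:
    """Build a genomic locus (flank + exons/introns + flank) around the
    final CDS; returns the structure and its locus name.  ``violated_intron``
    (1-based) gets non-splice-site ends, mimicking a mispredicted border."""
    lo, hi = intron_model.intron_length_range
    pieces = []
    exon_bounds = []
    pos = flank
    pieces.append(_random_dna(rng, flank))
    cuts = [0] + list(positions) + [len(cds)]
    strand = "+" if rng.random() < 0.5 else "-"
    for i in range(len(cuts) - 1):
        exon = cds[cuts[i] : cuts[i + 1]]
        pieces.append(exon)
        exon_bounds.append((pos, pos + len(exon)))
        pos += len(exon)
        if i < len(cuts) - 2:
            ilen = int(rng.integers(lo, hi + 1))
            interior = _random_dna(rng, ilen - 4)
            if violated_intron is not None and i + 1 == violated_intron:
                intron = "CT" + interior + "GG"
            elif rng.random() < intron_model.canonical_site_prob:
                intron = "GT" + interior + "AG"
            else:
                intron = "GC" + interior + "AG"
            pieces.append(intron)
            pos += ilen
    pieces.append(_random_dna(rng, flank))
    genomic = "".join(pieces)
    if strand == "-":
        G = len(genomic)
        genomic = revcomp(genomic)
        exon_bounds = [(G - e, G - s) for s, e in exon_bounds]
    return (
        GeneStructure(gene_id=gene_id, strand=strand, exons=exon_bounds, genomic=genomic),
        gene_id + "_locus",
    )


# ---------------------------------------------------------------------------
# corruption


def _shift_border(
    cds: str, positions: list[int], intron_index: int, shift_nt: int, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Slide intron ``intron_index`` (1-based) by +shift_nt: the donor and
    acceptor move together, so only that border's mark changes while the
    frame downstream is restored.  The absorbed nucleotides are resampled
    until no stop codon forms."""
    j = intron_index - 1
    c = positions[j]
    for _ in range(100):
        absorbed = "".join("GC"[i] for i in rng.integers(0, 2, size=shift_nt))
        new_cds = cds[:c] + absorbed + cds[c + shift_nt :]
        lo = max(0, (c // 3 - 1) * 3)
        hi = min(len(new_cds) - len(new_cds) % 3, ((c + shift_nt) // 3 + 2) * 3)
        window = new_cds[lo:hi]
        if not any(window[k : k + 3] in _STOPS for k in range(0, len(window), 3)):
            break
    new_positions = positions.copy()
    new_positions[j] = c + shift_nt
    return new_cds, new_positions


def _plant_frameshift(cds: str, positions: list[int], at: int) -> tuple[str, list[int]]:
    """Delete one nucleotide at CDS position ``at``."""
    new_cds = cds[:at] + cds[at + 1 :]
    new_positions = [c if c <= at else c - 1 for c in positions]
    return new_cds, new_positions


def _plant_stop(cds: str, codon_index: int) -> str:
    p = 3 * codon_index
    return cds[:p] + "TAA" + cds[p + 3 :]


def _safe_codon_indices(positions: list[int], cds_len: int, margin_nt: int = 9) -> list[int]:
    """Codon indices lying fully inside an exon, away from borders and the
    CDS ends."""
    cuts = [0] + list(positions) + [cds_len]
    safe = []
    for i in range(len(cuts) - 1):
        lo = cuts[i] + margin_nt
        hi = cuts[i + 1] - margin_nt
        first = -(-lo // 3)
        last = hi // 3 - 1
        safe.extend(range(first, last))
    return [c for c in safe if 1 <= c < cds_len // 3 - 1]


def corrupt_gene_structure(
    gs: GeneStructure, error_model: ErrorModel, seed: int
) -> tuple[GeneStructure, list[dict]]:
    """Apply the error model to an existing gene structure.

    Defect categories are drawn independently here (the caller controls
    rates); the defect log records every edit with enough detail to verify
    downstream detection.  Intron sequences are kept where unaffected.
    """
    rng = np.random.default_rng(seed)
    from coronin.gene_structure import intron_marks

    positions = [m.cds_nt_before for m in intron_marks(gs)]
    cds = gs.cds
    introns = [gs.intron_seq(i) for i in range(gs.n_introns)]
    log: list[dict] = []
    violated = None
    if positions and rng.random() < error_model.border_shift_rate:
        j = int(rng.integers(1, len(positions) + 1))
        old_phase = positions[j - 1] % 3
        cds, positions = _shift_border(
            cds, positions, j, error_model.border_shift_nt, rng
        )
        violated = j
        introns[j - 1] = "CT" + introns[j - 1][2:-2] + "GG"
        log.append(
            {
                "type": "border_shift",
                "intron_index": j,
                "shift_nt": error_model.border_shift_nt,
                "old_phase": old_phase,
                "new_phase": positions[j - 1] % 3,
            }
        )
    if rng.random() < error_model.frameshift_rate:
        for _ in range(error_model.n_frameshifts):
            safe = _safe_codon_indices(positions, len(cds))
            at = 3 * int(safe[int(rng.integers(0, len(safe)))])
            cds, positions = _plant_frameshift(cds, positions, at)
            log.append({"type": "frameshift", "cds_position": at})
    if rng.random() < error_model.stop_rate:
        for _ in range(error_model.n_stops):
            safe = _safe_codon_indices(positions, len(cds))
            codon = int(safe[int(rng.integers(0, len(safe)))])
            cds = _plant_stop(cds, codon)
            log.append({"type": "stop", "codon_index": codon})
    if rng.random() < error_model.truncation_rate:
        frag = rng.random() < error_model.fragment_prob_given_truncation
        lo, hi = (
            error_model.fragment_fraction_range
            if frag
            else error_model.partial_fraction_range
        )
        fraction = float(rng.uniform(lo, hi))
        n_res = len(cds) // 3
        keep = n_res - max(1, int(round(fraction * n_res)))
        cds = cds[: 3 * keep]
        positions = [c for c in positions if c < len(cds)]
        log.append({"type": "truncation", "fraction": fraction, "kept_residues": keep})

    if not log:
        return gs, []

    # rebuild the locus, reusing intron sequences where they survive
    flank = 50
    pieces = [gs.genomic[:flank] if len(gs.genomic) >= flank else _random_dna(rng, flank)]
    pos = len(pieces[0])
    exon_bounds = []
    cuts = [0] + positions + [len(cds)]
    for i in range(len(cuts) - 1):
        exon = cds[cuts[i] : cuts[i + 1]]
        exon_bounds.append((pos, pos + len(exon)))
        pieces.append(exon)
        pos += len(exon)
        if i < len(cuts) - 2:
            intron = introns[i] if i < len(introns) else "GT" + _random_dna(rng, 60) + "AG"
            pieces.append(intron)
            pos += len(intron)
    pieces.append(gs.genomic[-flank:] if len(gs.genomic) >= flank else _random_dna(rng, flank))
    genomic = "".join(pieces)
    new_gs = GeneStructure(
        gene_id=gs.gene_id, strand="+", exons=exon_bounds, genomic=genomic
    )
    return new_gs, log


# ---------------------------------------------------------------------------
# ground truth and family containers


@dataclass
class GroundTruth:
    classes: dict[str, str]
    species: dict[str, str]
    completeness: dict[str, str]
    missing_fraction: dict[str, float]
    expected_length: dict[str, int]
    pseudogene: dict[str, bool]
    has_sequence: dict[str, bool]
    oligomer: dict[str, str]
    motif_variant: dict[str, Optional[str]]
    motif_start: dict[str, int]
    cc_region: dict[str, tuple[int, int]]
    intron_marks: dict[str, list[tuple[int, int, int]]]
    expected_phases: dict[str, list[int]]
    defects: dict[str, list[dict]]
    mxe: dict[str, dict]
    architecture: dict[str, str]
    domain_rows: list[str]
    outgroup: Optional[str]
    conserved_phases: list[int]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True, default=list)

    def labeled_records(self, records: list[SequenceRecord]) -> list[SequenceRecord]:
        """Copies of the records with the true class, completeness and
        pseudogene metadata attached (for reporting)."""
        out = []
        for r in records:
            out.append(
                SequenceRecord(
                    id=r.id,
                    protein=r.protein,
                    species=r.species,
                    class_label=self.classes[r.id],
                    completeness=(
                        None if self.pseudogene[r.id] else self.completeness[r.id]
                    ),
                    pseudogene=self.pseudogene[r.id],
                    from_wgs=r.from_wgs,
                    has_sequence=self.has_sequence[r.id],
                )
            )
        return out


@dataclass
class SimulatedFamily:
    params: SimParams
    records: list[SequenceRecord]
    structures: dict[str, GeneStructure]
    locus_names: dict[str, str]
    alignment: AlignmentBlock  # full-length short coronins
    domain_alignment: AlignmentBlock  # all coronin domains, 390 columns
    ca_c_alignment: Optional[AlignmentBlock]
    ca_a_alignment: Optional[AlignmentBlock]
    annotations: pd.DataFrame
    species_tree_newick: str
    gene_tree_newick: str
    truth: GroundTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "proteins.fasta")
        write_alignment(self.alignment, outdir / "shorts_alignment.fasta")
        write_alignment(self.domain_alignment, outdir / "coronin_domains.fasta")
        genomic = {
            self.locus_names[g]: gs.genomic for g, gs in self.structures.items()
        }
        write_genomic_fasta(genomic, outdir / "loci.fasta")
        write_gene_structures(
            list(self.structures.values()),
            outdir / "genes.gff3",
            seqids=self.locus_names,
        )
        write_domain_annotations(self.annotations, outdir / "annotations.tsv")
        (outdir / "species_tree.nwk").write_text(self.species_tree_newick + "\n")
        (outdir / "gene_tree.nwk").write_text(self.gene_tree_newick + "\n")
        (outdir / "ground_truth.json").write_text(self.truth.to_json() + "\n")


# ---------------------------------------------------------------------------
# the generator


def simulate_family(params: SimParams) -> SimulatedFamily:
    rng = np.random.default_rng(params.seed)
    tree, metazoans, others = _species_tree(params, rng)
    species = sorted(metazoans + others)

    # class presence (ancient genes, lineage-specific losses)
    s3 = sorted(
        sp for sp in species if rng.random() < params.class_events.class3_fraction
    )
    s4 = sorted(
        sp for sp in species if rng.random() < params.class_events.class4_fraction
    )
    if len(s3) == 1:
        s3 = []
    if len(s4) == 1:
        s4 = []

    # ancestral regions
    u_len = int(rng.integers(*params.unique_length_range))
    cc_len = int(rng.integers(*params.cc_length_range))
    anc_coro = _random_protein(rng, params.coro_length)
    anc_unique = _random_protein(rng, u_len)
    anc_cc = _random_protein(rng, cc_len)
    # classical motif in the ancestral coiled-coil
    for pos, aa in zip(range(6), "RLKSVE"):
        anc_cc[MOTIF_OFFSET_IN_CC + pos] = AA_INDEX[aa]

    short_model = _GeneModel(
        [
            _Region("CORO", anc_coro.copy()),
            _Region("U", anc_unique.copy()),
            _Region("CC", anc_cc.copy()),
        ]
    )
    # tandem fusion: the C-terminal domain stays closer to the short-coronin
    # ancestor than the N-terminal one
    coro3_model = _GeneModel(
        [
            _Region("CORO", _evolve(anc_coro, REGION_RATES["CORO"], 6.0, rng)),
            _Region("X", _random_protein(rng, 40)),
            _Region("CORO", _evolve(anc_coro, REGION_RATES["CORO"], 2.0, rng)),
            _Region("U", _random_protein(rng, 10)),
            _Region("CA_C", _biased_protein(rng, 14, "LIVFMA") ),
            _Region("CA_L", _random_protein(rng, 8)),
            _Region("CA_A", _biased_protein(rng, 12, "DE")),
        ]
    )
    coro3_model.regions[4].seq[-1] = AA_INDEX["K"]  # basic residue closing the C region
    coro4_model = _GeneModel(
        [
            _Region("CORO", _evolve(anc_coro, REGION_RATES["CORO"], 3.0, rng)),
            _Region("GAP", _random_protein(rng, 10)),
        ]
        + [
            r
            for i in range(3)
            for r in (
                _Region("PH", _random_protein(rng, 100)),
                _Region("GAP", _random_protein(rng, 5)),
            )
        ]
        + [
            r
            for i in range(5)
            for r in (
                _Region("GEL", _random_protein(rng, 110)),
                _Region("GAP", _random_protein(rng, 5)),
            )
        ]
        + [_Region("VHP", _random_protein(rng, 35))]
    )

    # evolve down the species tree
    tips: dict[str, dict[str, _GeneModel]] = {}

    def walk(node: _SpNode, state: dict[str, _GeneModel]) -> None:
        state = {g: m.evolve(node.length, rng) for g, m in state.items()}
        if node.is_metazoan_root and "short" in state:
            base = state.pop("short")
            state["coro1"] = base.evolve(0.1, rng)
            state["coro2"] = base.evolve(0.1, rng)
        if node.is_leaf:
            tips[node.name] = state
        else:
            for child in node.children:
                walk(child, state)

    walk(tree, {"short": short_model, "coro3": coro3_model, "coro4": coro4_model})

    # conserved intron sites
    positions0, conserved_phases = _conserved_intron_positions(params, rng)
    c1, c2 = positions0[0], positions0[1]
    r1, r2 = c1 // 3, c2 // 3
    mxe_len = r2 - r1  # residues in the duplicable exon

    # enumerate genes in deterministic order
    gene_plan: list[tuple[str, str, str]] = []  # (gene_id, species, kind)
    for sp in species:
        if sp in metazoans:
            gene_plan.append((f"{sp}_coro1", sp, "class-1"))
            gene_plan.append((f"{sp}_coro2", sp, "class-2"))
        else:
            gene_plan.append((f"{sp}_short", sp, "unclassified"))
        if sp in s3:
            gene_plan.append((f"{sp}_coro3", sp, "class-3"))
        if sp in s4:
            gene_plan.append((f"{sp}_coro4", sp, "class-4"))

    em = params.error_model

    # one defect category per gene, drawn up front
    defect_by_gene: dict[str, str] = {}
    for gene_id, _, _ in gene_plan:
        defect = "none"
        u = rng.random()
        acc = 0.0
        for cat, rate in (
            ("pseudogene", em.pseudogene_rate),
            ("border_shift", em.border_shift_rate),
            ("stop", em.stop_rate),
            ("truncation", em.truncation_rate),
        ):
            acc += rate
            if u < acc:
                defect = cat
                break
        defect_by_gene[gene_id] = defect

    # plant MXE pairs only in class-1 genes whose alignment row and intron
    # chain survive intact, so the duplicated exon's borders support each
    # other across the >= 3 carriers (as shared ancestral duplications do)
    class1_ids = [
        g
        for g, _, k in gene_plan
        if k == "class-1" and defect_by_gene[g] in ("none", "stop")
    ]
    n_mxe = int(round(params.mxe_fraction * len(class1_ids)))
    if 0 < n_mxe < 3:
        n_mxe = 3 if len(class1_ids) >= 3 else 0
    mxe_ids = set(
        class1_ids[i] for i in rng.choice(len(class1_ids), size=n_mxe, replace=False)
    ) if n_mxe else set()
    variant_names = sorted(params.motif_variant_frequencies)
    variant_probs = np.array([params.motif_variant_frequencies[v] for v in variant_names])

    truth = GroundTruth(
        classes={}, species={}, completeness={}, missing_fraction={},
        expected_length={}, pseudogene={}, has_sequence={}, oligomer={},
        motif_variant={}, motif_start={}, cc_region={}, intron_marks={},
        expected_phases={}, defects={}, mxe={}, architecture={},
        domain_rows=[], outgroup=None, conserved_phases=conserved_phases,
    )
    records: list[SequenceRecord] = []
    structures: dict[str, GeneStructure] = {}
    locus_names: dict[str, str] = {}
    annotations_rows: list[dict] = []
    short_rows: list[tuple[str, str]] = []
    domain_rows: list[tuple[str, str]] = []
    ca_c_rows: list[tuple[str, str]] = []
    ca_a_rows: list[tuple[str, str]] = []

    any_mxe = bool(mxe_ids)
    insert_w = mxe_len if any_mxe else 0

    for gene_id, sp, kind in gene_plan:
        model = tips[sp][
            {"class-1": "coro1", "class-2": "coro2", "unclassified": "short",
             "class-3": "coro3", "class-4": "coro4"}[kind]
        ]
        coords = model.coords()
        protein = list(model.protein())
        is_short = kind in ("class-1", "class-2", "unclassified")
        motif_variant = None
        motif_start = 0
        cc_start = cc_end = 0
        if is_short:
            cc_start, cc_end = coords["CC"][0]
            motif_start0 = cc_start - 1 + MOTIF_OFFSET_IN_CC
            motif_variant = variant_names[
                int(rng.choice(len(variant_names), p=variant_probs))
            ]
            tail_start0 = max(0, len(protein) - 60)
            _plant_motif(protein, motif_start0, motif_variant, tail_start0, rng)
            motif_start = motif_start0 + 1

        # mutually exclusive exon duplication (class-1 only)
        mxe_planted = gene_id in mxe_ids
        clean_positions = list(positions0)
        if mxe_planted:
            exon_aa = protein[r1:r2]
            copy_aa = exon_aa.copy()
            n_mut = max(1, int(round((1 - params.mxe_identity) * mxe_len)))
            for i in rng.choice(mxe_len, size=n_mut, replace=False):
                copy_aa[i] = AA20[(AA_INDEX[copy_aa[i]] + int(rng.integers(1, 20))) % 20]
            identity = sum(a == b for a, b in zip(exon_aa, copy_aa)) / mxe_len
            protein = protein[:r2] + copy_aa + protein[r2:]
            clean_positions = (
                positions0[:2]
                + [c2 + 3 * mxe_len]
                + [c + 3 * mxe_len for c in positions0[2:]]
            )
            truth.mxe[gene_id] = {
                "exon_indices": [2, 3],
                "identity": identity,
                "inserted_residues": mxe_len,
            }
            if is_short:
                motif_start += mxe_len
                cc_start += mxe_len
                cc_end += mxe_len

        protein_str = "".join(protein)
        full_len = len(protein_str)
        cds = _back_translate(protein_str, rng) + "TAA"

        defect = defect_by_gene[gene_id]
        positions = list(clean_positions)
        clean_phases = [c % 3 for c in clean_positions]
        defects_log: list[dict] = []
        violated_intron = None
        missing_fraction = 0.0
        is_pseudo = False

        if defect == "border_shift":
            j = int(rng.integers(1, len(positions) + 1))
            cds, positions = _shift_border(cds, positions, j, em.border_shift_nt, rng)
            violated_intron = j
            defects_log.append(
                {"type": "border_shift", "intron_index": j, "shift_nt": em.border_shift_nt}
            )
        elif defect == "pseudogene":
            is_pseudo = True
            used_exons: set[int] = set()
            for _ in range(em.n_frameshifts):
                safe = _safe_codon_indices(positions, len(cds))
                cuts = [0] + positions + [len(cds)]
                choices = [
                    c for c in safe
                    if next(i for i in range(len(cuts) - 1) if cuts[i] <= 3 * c < cuts[i + 1])
                    not in used_exons
                ] or safe
                at_codon = int(choices[int(rng.integers(0, len(choices)))])
                used_exons.add(
                    next(i for i in range(len(positions) + 1)
                         if ([0] + positions + [len(cds)])[i] <= 3 * at_codon
                         < ([0] + positions + [len(cds)])[i + 1])
                )
                cds, positions = _plant_frameshift(cds, positions, 3 * at_codon)
                defects_log.append({"type": "frameshift", "cds_position": 3 * at_codon})
            for _ in range(em.n_stops):
                safe = _safe_codon_indices(positions, len(cds))
                codon = int(safe[int(rng.integers(0, len(safe)))])
                cds = _plant_stop(cds, codon)
                defects_log.append({"type": "stop", "codon_index": codon})
        elif defect == "stop":
            # single isolated stop: keep it inside the coronin domain so the
            # coiled-coil motif stays intact
            safe = [
                c for c in _safe_codon_indices(positions, len(cds))
                if c < params.coro_length - 5
            ]
            codon = int(safe[int(rng.integers(0, len(safe)))])
            cds = _plant_stop(cds, codon)
            defects_log.append({"type": "stop", "codon_index": codon})
        elif defect == "truncation":
            frag = rng.random() < em.fragment_prob_given_truncation
            lo, hi = em.fragment_fraction_range if frag else em.partial_fraction_range
            fraction = float(rng.uniform(lo, hi))
            n_remove = max(1, int(round(fraction * full_len)))
            keep = full_len - n_remove
            cds = cds[: 3 * keep]  # truncated genes lose the stop codon too
            positions = [c for c in positions if c < len(cds)]
            clean_phases = clean_phases[: len(positions)]
            missing_fraction = n_remove / full_len
            defects_log.append(
                {"type": "truncation", "fraction": missing_fraction, "kept_residues": keep}
            )

        observed_protein = _translate_cds(cds).replace("*", "X")
        category = (
            "Complete"
            if missing_fraction == 0
            else ("Partial" if missing_fraction <= 0.05 else "Fragment")
        )
        has_seq = True
        if is_pseudo and rng.random() < 0.4:
            has_seq = False

        # a truncation may have removed (part of) the coiled-coil motif
        motif_intact = (
            is_short
            and not is_pseudo
            and len(observed_protein) >= motif_start + 5
        )
        cc_end_obs = min(cc_end, len(observed_protein))

        gs, locus = _materialize(
            gene_id, cds, positions, rng, params.intron_model,
            violated_intron=violated_intron,
        )
        structures[gene_id] = gs
        locus_names[gene_id] = locus
        records.append(
            SequenceRecord(
                id=gene_id,
                protein=observed_protein,
                species=sp,
                from_wgs=bool(rng.random() < 0.97),
            )
        )

        # annotations for the pipeline (coiled-coils and villin-derived blocks)
        if (
            is_short and not is_pseudo and category != "Fragment"
            and cc_end_obs > cc_start
        ):
            annotations_rows.append(
                dict(seq_id=gene_id, domain_name="CC", start=cc_start, end=cc_end_obs,
                     source="synthetic_annotation")
            )
        if kind == "class-4":
            for name, key in (("PH", "PH"), ("GEL", "GEL"), ("VHP", "VHP")):
                for s_, e_ in coords[key]:
                    annotations_rows.append(
                        dict(seq_id=gene_id, domain_name=name, start=s_, end=e_,
                             source="synthetic_annotation")
                    )

        # ground truth
        truth.classes[gene_id] = kind
        truth.species[gene_id] = sp
        truth.completeness[gene_id] = category
        truth.missing_fraction[gene_id] = missing_fraction
        truth.expected_length[gene_id] = full_len
        truth.pseudogene[gene_id] = is_pseudo
        truth.has_sequence[gene_id] = has_seq
        truth.motif_variant[gene_id] = motif_variant if motif_intact else None
        truth.motif_start[gene_id] = motif_start if motif_intact else 0
        if is_short and not is_pseudo:
            if category == "Fragment" or cc_end_obs <= cc_start:
                # the whole coiled-coil is lost with the truncated tail
                truth.oligomer[gene_id] = "no_coiled_coil"
            elif motif_intact:
                truth.cc_region[gene_id] = (cc_start, cc_end_obs)
                truth.oligomer[gene_id] = VARIANT_STATES[motif_variant]
            else:
                truth.cc_region[gene_id] = (cc_start, cc_end_obs)
                truth.oligomer[gene_id] = "unknown"
        elif is_short:
            truth.oligomer[gene_id] = "unknown"
        else:
            truth.oligomer[gene_id] = "no_coiled_coil"
        truth.intron_marks[gene_id] = _marks_from_positions(positions)
        truth.expected_phases[gene_id] = clean_phases
        truth.defects[gene_id] = defects_log
        if kind == "class-3":
            truth.architecture[gene_id] = "CORO–X–CORO–CA"
        elif kind == "class-4":
            truth.architecture[gene_id] = "CORO–PH×3–GEL×5–VHP"
        else:
            truth.architecture[gene_id] = "CORO–U–CC"

        # alignment rows (complete/partial, non-pseudogene); the duplicated
        # MXE exon occupies a shared block of insert columns, gapped in all
        # other rows, so downstream intron projections stay comparable
        include = not is_pseudo and category in ("Complete", "Partial")
        padded = observed_protein + "-" * (full_len - len(observed_protein))
        if include and is_short:
            if mxe_planted:
                row = padded  # insert block already at columns r2+1..r2+insert_w
            else:
                row = padded[:r2] + "-" * insert_w + padded[r2:]
            short_rows.append((gene_id, row))
        if include:
            if is_short:
                if mxe_planted:
                    dom = padded[:r2] + padded[r2 + mxe_len : params.coro_length + mxe_len]
                else:
                    dom = padded[: params.coro_length]
                domain_rows.append((gene_id, dom))
                truth.domain_rows.append(gene_id)
            elif kind == "class-3":
                (n_s, n_e), (c_s, c_e) = coords["CORO"]
                domain_rows.append((gene_id + "_Nd", padded[n_s - 1 : n_e]))
                domain_rows.append((gene_id + "_Cd", padded[c_s - 1 : c_e]))
                truth.domain_rows.extend([gene_id + "_Nd", gene_id + "_Cd"])
                cs, ce = coords["CA_C"][0]
                as_, ae = coords["CA_A"][0]
                if len(padded) >= ae and "-" not in padded[cs - 1 : ae]:
                    ca_c_rows.append((gene_id, padded[cs - 1 : ce]))
                    ca_a_rows.append((gene_id, padded[as_ - 1 : ae]))
            elif kind == "class-4":
                s_, e_ = coords["CORO"][0]
                domain_rows.append((gene_id, padded[s_ - 1 : e_]))
                truth.domain_rows.append(gene_id)

    # gene tree over the coronin domains that enter the phylogeny
    included = set(truth.domain_rows)

    def mapper_for(suffix: str, kinds: tuple[str, ...]):
        def mapper(sp_name: str):
            for gid, sp2, k in gene_plan:
                if sp2 == sp_name and k in kinds:
                    label = gid + suffix
                    if label in included:
                        return label
            return None

        return mapper

    met_clade = tree.children[1]
    non_clade = tree.children[0]
    parts = []
    short_parts = []
    non_sub = _induced_newick(non_clade, mapper_for("", ("unclassified",)))
    if non_sub:
        short_parts.append(f"{non_sub[0]}:{non_sub[1]:.5f}")
    c1_sub = _induced_newick(met_clade, mapper_for("", ("class-1",)))
    c2_sub = _induced_newick(met_clade, mapper_for("", ("class-2",)))
    met_parts = [f"{s}:{ln:.5f}" for s, ln in (c1_sub, c2_sub) if s is not None]
    if len(met_parts) == 2:
        short_parts.append(f"({','.join(met_parts)}):0.10000")
    elif met_parts:
        short_parts.append(met_parts[0])
    shorts_clade = (
        f"({','.join(short_parts)}):0.15000" if len(short_parts) > 1
        else (short_parts[0] if short_parts else None)
    )
    c3c = _induced_newick(tree, mapper_for("_Cd", ("class-3",)))
    c3n = _induced_newick(tree, mapper_for("_Nd", ("class-3",)))
    c4 = _induced_newick(tree, mapper_for("", ("class-4",)))
    inner_parts = [p for p in (shorts_clade,
                               f"{c3c[0]}:{c3c[1] + 0.25:.5f}" if c3c else None) if p]
    inner = f"({','.join(inner_parts)}):0.20000" if len(inner_parts) > 1 else inner_parts[0]
    top = [inner]
    if c3n:
        top.append(f"{c3n[0]}:{c3n[1] + 0.45:.5f}")
    if c4:
        top.append(f"{c4[0]}:{c4[1] + 0.55:.5f}")
    gene_tree_newick = f"({','.join(top)});"

    for gid, _, k in gene_plan:
        if k == "class-4" and gid in included:
            truth.outgroup = gid
            break
    if truth.outgroup is None:
        for gid, _, k in gene_plan:
            if k == "class-3" and gid + "_Nd" in included:
                truth.outgroup = gid + "_Nd"
                break

    annotations = pd.DataFrame(
        annotations_rows, columns=["seq_id", "domain_name", "start", "end", "source"]
    )
    return SimulatedFamily(
        params=params,
        records=records,
        structures=structures,
        locus_names=locus_names,
        alignment=AlignmentBlock(short_rows),
        domain_alignment=AlignmentBlock(domain_rows),
        ca_c_alignment=AlignmentBlock(ca_c_rows) if len(ca_c_rows) >= 2 else None,
        ca_a_alignment=AlignmentBlock(ca_a_rows) if len(ca_a_rows) >= 2 else None,
        annotations=annotations,
        species_tree_newick=_newick(tree),
        gene_tree_newick=gene_tree_newick,
        truth=truth,
    )
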