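"""Domain detection, trimerization-motif scanning and architecture assembly.

The coronin domain (~390 residues: seven-bladed WD40 beta-propeller plus
its C-terminal extension) is detected with a profile (PSSM) built from a
trusted domain alignment.  The C-terminal coiled-coil of short coronins is
scanned for the trimerization motif R-[ILVM]-X-X-[ILV]-E, whose arginine-
glutamate salt bridge shields the hydrophobic positions 2 and 5; the
oligomeric state is predicted from the motif variant using the
experimentally established substitution effects.  The CA domain of tandem
coronins (a hydrophobic central region followed, after a variable linker,
by an acidic region, as in WASP-family proteins) is found with a pair of
profiles.  Finally, per-sequence domain hits — profile hits plus external
annotations for non-coronin domains (PH, gelsolin, VHP, ...) — are
assembled into a canonical architecture string.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from coronin.seqio import AA20, AlignmentBlock

AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

DOMAIN_NAMES = ("CORO", "CC", "CA", "PH", "GEL", "VHP", "DUT", "GLYK", "other")

SCORE_FLOOR = -20.0  # bits; cap for log-odds of unobserved residues at pc=0

DEFAULT_SCAN_THRESHOLD = 0.5  # bits per column
DEFAULT_TAIL_WINDOW = 60  # residues scanned for the motif without a CC annotation
DEFAULT_MAX_LINKER = 40  # max residues between the C and A regions of a CA domain
DEFAULT_MIN_LINKER = 15  # min gap rendered as a unique-region token

HYDROPHOBIC_P2 = set("ILVM")
HYDROPHOBIC_P5 = set("ILV")

VARIANT_RANK = {
    "classical": 0,
    "swapped": 1,
    "p1_sub": 2,
    "p6_sub": 3,
    "p2/p5_sub": 4,
}


@dataclass
class Pssm:
    """Log-odds profile over the 20 amino acids.

    score(col, aa) = log2(((count + pseudocount * bg) / (n + pseudocount))
    / bg), with gap cells excluded from the counts.
    """

    width: int
    scores: np.ndarray  # (width, 20), bits
    background: np.ndarray  # (20,)
    pseudocount: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "width": self.width,
                "scores": self.scores.tolist(),
                "background": self.background.tolist(),
                "pseudocount": self.pseudocount,
            }
        )

    @classmethod
    def from_json(cls, data: str) -> "Pssm":
        d = json.loads(data)
        return cls(
            width=d["width"],
            scores=np.asarray(d["scores"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            pseudocount=d["pseudocount"],
        )

    def consensus_score(self) -> float:
        """Upper bound of the sliding-window score (column maxima)."""
        return float(self.scores.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(AA20[i] for i in self.scores.argmax(axis=1))


@dataclass(frozen=True)
class DomainHit:
    seq_id: str
    domain_name: str
    start: int  # 1-based inclusive
    end: int
    score: float = 0.0
    source: str = "pssm"  # pssm | pattern | annotation

    def __post_init__(self) -> None:
        assert 1 <= self.start <= self.end
        assert self.domain_name in DOMAIN_NAMES

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 1-based
    residues: str  # the 6-residue window
    variant: str  # classical | swapped | p1_sub(X) | p6_sub(X) | p2/p5_sub

    @property
    def positions(self) -> dict[str, str]:
        return {f"p{i + 1}": aa for i, aa in enumerate(self.residues)}


@dataclass(frozen=True)
class OligomerCall:
    seq_id: str
    state: str
    rule_id: str
    evidence: Optional[MotifHit]


@dataclass
class DomainArchitecture:
    seq_id: str
    hits: list[DomainHit]
    architecture_string: str = field(init=False)

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: (h.start, h.end))
        for a, b in zip(self.hits, self.hits[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.seq_id}: overlapping hits {a.domain_name} and "
                    f"{b.domain_name}; resolve overlaps before assembly"
                )
        self.architecture_string = _architecture_string(self.hits)


# ---------------------------------------------------------------------------
# PSSM construction and scanning


def build_pssm(
    aln: AlignmentBlock,
    columns: Optional[Sequence[int]] = None,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 1.0,
) -> Pssm:
    """Build a log-odds profile from alignment columns (1-based; default
    all).  Gap and unknown (X) cells are excluded from the counts; an
    all-gap column is an error.
    """
    cols = list(columns) if columns is not None else list(range(1, aln.length + 1))
    if not cols:
        raise ValueError("empty column selection")
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 alignment rows")
    bg = (
        np.full(20, 1.0 / 20)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background frequencies must sum to 1")
    width = len(cols)
    scores = np.empty((width, 20), dtype=float)
    for j, col in enumerate(cols):
        if not 1 <= col <= aln.length:
            raise ValueError(f"column {col} outside alignment of length {aln.length}")
        counts = np.zeros(20)
        for _, row in aln.rows:
            aa = row[col - 1]
            if aa in AA_INDEX:
                counts[AA_INDEX[aa]] += 1
        n = counts.sum()
        if n == 0:
            raise ValueError(f"column {col} contains only gaps")
        with np.errstate(divide="ignore"):
            freq = (counts + pseudocount * bg) / (n + pseudocount)
            scores[j] = np.maximum(np.log2(freq / bg), SCORE_FLOOR)
    return Pssm(width=width, scores=scores, background=bg, pseudocount=pseudocount)


def scan_domain(
    seq: str,
    pssm: Pssm,
    threshold_bits_per_column: float = DEFAULT_SCAN_THRESHOLD,
    seq_id: str = "",
    domain_name: str = "CORO",
) -> list[DomainHit]:
    """Slide the profile along the sequence and report non-overlapping
    hits above ``threshold * width`` total bits, greedily by score.

    Unknown residues (X) contribute 0 bits (background-neutral), so a
    tandem-domain protein yields two separate hits.
    """
    L = len(seq)
    w = pssm.width
    if L < w:
        return []
    idx = np.array([AA_INDEX.get(aa, -1) for aa in seq])
    # per-profile-column positional scores; X columns padded with 0
    padded = np.hstack([pssm.scores, np.zeros((w, 1))])  # index -1 -> 0.0
    n_windows = L - w + 1
    totals = np.zeros(n_windows)
    for j in range(w):
        totals += padded[j, idx[j : j + n_windows]]
    threshold = threshold_bits_per_column * w
    order = sorted(
        (i for i in range(n_windows) if totals[i] >= threshold),
        key=lambda i: (-totals[i], i),
    )
    hits: list[DomainHit] = []
    taken: list[tuple[int, int]] = []
    for i in order:
        s, e = i + 1, i + w  # 1-based inclusive
        if all(e < ts or s > te for ts, te in taken):
            taken.append((s, e))
            hits.append(
                DomainHit(
                    seq_id=seq_id,
                    domain_name=domain_name,
                    start=s,
                    end=e,
                    score=float(totals[i]),
                    source="pssm",
                )
            )
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# Trimerization motif


def classify_motif_window(window: str) -> Optional[str]:
    """Variant class of a 6-residue window, or None if it is not a motif.

    classical  R-[ILVM]-X-X-[ILV]-E
    swapped    E-[ILVM]-X-X-[ILV]-R  (salt bridge reversed)
    p1_sub(Y)  Y-[ILVM]-X-X-[ILV]-E, Y != R
    p6_sub(Y)  R-[ILVM]-X-X-[ILV]-Y, Y != E
    p2/p5_sub  R-X-X-X-X-E with a non-hydrophobic position 2 or 5
    """
    if len(window) != 6:
        raise ValueError("motif window must be 6 residues")
    p1, p2, _, _, p5, p6 = window
    hydro = p2 in HYDROPHOBIC_P2 and p5 in HYDROPHOBIC_P5
    if hydro:
        if p1 == "R" and p6 == "E":
            return "classical"
        if p1 == "E" and p6 == "R":
            return "swapped"
        if p6 == "E":
            sub = p1 if p1 in "KQA" else "other"
            return f"p1_sub({sub})"
        if p1 == "R":
            sub = p6 if p6 == "Q" else "other"
            return f"p6_sub({sub})"
        return None
    if p1 == "R" and p6 == "E":
        return "p2/p5_sub"
    return None


def _variant_rank(variant: str) -> int:
    base = variant.split("(")[0]
    return VARIANT_RANK[base]


def find_trimerization_motif(
    seq: str,
    cc_region: Optional[tuple[int, int]] = None,
    seq_id: str = "",
    tail_window: int = DEFAULT_TAIL_WINDOW,
) -> Optional[MotifHit]:
    """Scan the coiled-coil (or, absent an annotation, the C-terminal
    ``tail_window`` residues) for the trimerization motif.

    A classical match is preferred; otherwise the best variant by rank
    (classical > swapped > p1_sub > p6_sub > p2/p5_sub), leftmost on ties.
    """
    if cc_region is not None:
        lo, hi = cc_region
        lo = max(1, lo)
        hi = min(len(seq), hi)
    else:
        lo, hi = max(1, len(seq) - tail_window + 1), len(seq)
    best: Optional[tuple[int, int, str, str]] = None
    for start in range(lo, hi - 4):  # 1-based window starts
        window = seq[start - 1 : start + 5]
        variant = classify_motif_window(window)
        if variant is None:
            continue
        rank = _variant_rank(variant)
        if best is None or rank < best[0]:
            best = (rank, start, window, variant)
    if best is None:
        return None
    _, start, window, variant = best
    return MotifHit(seq_id=seq_id, start=start, residues=window, variant=variant)


#: variant -> (state, rule id).  The effects follow the coiled-coil
#: mutagenesis record: the classical motif forms parallel trimers; R->K
#: gives a concentration-dependent trimer/tetramer equilibrium; R->A (and
#: norleucine, unrepresentable in sequence) gives tetramers; R->Q gives
#: tetramers (matrilin-1); a reversed salt bridge is expected to trimerize;
#: E6->Q has not been characterized.
OLIGOMER_RULES: dict[str, tuple[str, str]] = {
    "classical": ("trimer", "classical_motif_trimer"),
    "swapped": ("trimer", "salt_bridge_swap_trimer"),
    "p1_sub(K)": ("trimer_tetramer_equilibrium", "arg_to_lys_equilibrium"),
    "p1_sub(A)": ("tetramer", "arg_to_ala_tetramer"),
    "p1_sub(Q)": ("tetramer", "arg_to_gln_tetramer"),
    "p1_sub(other)": ("unknown", "uncharacterized_p1_substitution"),
    "p6_sub(Q)": ("unknown", "glu6_to_gln_uncharacterized"),
    "p6_sub(other)": ("unknown", "uncharacterized_p6_substitution"),
    "p2/p5_sub": ("unknown", "hydrophobic_core_substitution"),
}


def predict_oligomer(hit: Optional[MotifHit], has_cc: bool = True) -> OligomerCall:
    """Map a motif hit (or its absence) to a predicted oligomeric state."""
    seq_id = hit.seq_id if hit is not None else ""
    if not has_cc:
        return OligomerCall(seq_id, "no_coiled_coil", "no_coiled_coil", None)
    if hit is None:
        return OligomerCall(seq_id, "unknown", "no_motif", None)
    state, rule_id = OLIGOMER_RULES[hit.variant]
    return OligomerCall(seq_id, state, rule_id, hit)


# ---------------------------------------------------------------------------
# CA domain


def find_ca_domain(
    seq: str,
    c_profile: Pssm,
    a_profile: Pssm,
    max_linker: int = DEFAULT_MAX_LINKER,
    threshold_bits_per_column: float = DEFAULT_SCAN_THRESHOLD,
    seq_id: str = "",
) -> Optional[DomainHit]:
    """Find a CA domain: a central (C) region hit followed, within
    ``max_linker`` residues, by an acidic (A) region hit.

    The two regions are profile matches; the linker between them is of
    variable length, hence the explicit bound instead of a joint profile.
    """
    c_hits = scan_domain(
        seq, c_profile, threshold_bits_per_column, seq_id=seq_id, domain_name="other"
    )
    a_hits = scan_domain(
        seq, a_profile, threshold_bits_per_column, seq_id=seq_id, domain_name="other"
    )
    best: Optional[tuple[float, DomainHit]] = None
    for c in c_hits:
        for a in a_hits:
            linker = a.start - c.end - 1
            if 0 <= linker <= max_linker:
                combined = DomainHit(
                    seq_id=seq_id,
                    domain_name="CA",
                    start=c.start,
                    end=a.end,
                    score=c.score + a.score,
                    source="pssm",
                )
                if best is None or combined.score > best[0]:
                    best = (combined.score, combined)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# Architecture assembly

_SOURCE_PRIORITY = {"annotation": 2, "pssm": 1, "pattern": 0}
_LINKER_TOKEN_AFTER_GAP = {"CC": "U", "CORO": "X"}


def resolve_overlaps(hits: Iterable[DomainHit]) -> list[DomainHit]:
    """Drop the weaker of any two overlapping hits (score, then source
    priority annotation > pssm > pattern)."""
    ranked = sorted(
        hits,
        key=lambda h: (-h.score, -_SOURCE_PRIORITY[h.source], h.start),
    )
    kept: list[DomainHit] = []
    for h in ranked:
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def _architecture_string(hits: Sequence[DomainHit], min_linker: int = DEFAULT_MIN_LINKER) -> str:
    """Canonical architecture string.

    Runs of the same domain collapse to ``NAME×n``.  The unique region of
    a short coronin (the stretch between the coronin domain and the
    coiled-coil) is rendered as ``U``, the insertion between tandem
    coronin domains as ``X``; both only when the gap is at least
    ``min_linker`` residues.
    """
    if not hits:
        return ""
    tokens: list[str] = []
    run_name, run_count = hits[0].domain_name, 1
    prev = hits[0]
    for h in hits[1:]:
        gap = h.start - prev.end - 1
        linker = None
        if gap >= min_linker and h.domain_name in _LINKER_TOKEN_AFTER_GAP:
            linker = _LINKER_TOKEN_AFTER_GAP[h.domain_name]
        if h.domain_name == run_name and linker is None:
            run_count += 1
        else:
            tokens.append(run_name if run_count == 1 else f"{run_name}×{run_count}")
            if linker is not None:
                tokens.append(linker)
            run_name, run_count = h.domain_name, 1
        prev = h
    tokens.append(run_name if run_count == 1 else f"{run_name}×{run_count}")
    return "–".join(tokens)


def assemble_architecture(seq_id: str, hits: Iterable[DomainHit]) -> DomainArchitecture:
    """Resolve overlaps and emit the canonical architecture for one
    sequence."""
    resolved = resolve_overlaps(hits)
    return DomainArchitecture(seq_id=seq_id, hits=resolved)


def hits_from_annotations(annotations: pd.DataFrame, seq_id: str) -> list[DomainHit]:
    """Convert external annotation rows (seqio TSV) for one sequence into
    DomainHits with source='annotation'."""
    sub = annotations[annotations["seq_id"] == seq_id]
    hits = []
    for _, row in sub.iterrows():
        name = row["domain_name"] if row["domain_name"] in DOMAIN_NAMES else "other"
        hits.append(
            DomainHit(
                seq_id=seq_id,
                domain_name=name,
                start=int(row["start"]),
                end=int(row["end"]),
                score=float("inf"),
                source="annotation",
            )
        )
    return hits
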