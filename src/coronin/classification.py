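"""Class assignment from tree grouping plus distance/NJ and logo utilities.

Coronin classes are defined jointly by domain architecture and by
monophyletic grouping in the coronin-domain tree: class-1 and class-2 are
the two metazoan/choanoflagellate short-coronin groups (tree evidence
required), class-3 are the tandem coronins and class-4 the villin-fused
coronins (architecture evidence required, with a tree-supported exception
for bare-domain class-4 members).  Short coronins outside the metazoan
duplication are equally related to class-1 and class-2 and remain
unclassified.

The module also provides the supporting numerics: pairwise identity
matrices over alignment regions, a small neighbor-joining builder (exact
on additive matrices) for synthetic tests, and sequence-logo information
content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from coronin.seqio import AA20, AlignmentBlock

MIN_SHARED_COLUMNS = 10

LOG2_20 = math.log2(20.0)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of distances = 1 - fractional identity over
    mutually non-gap columns; pairs with too few shared columns are NaN
    and recorded in ``undefined_pairs``."""

    ids: list[str]
    matrix: np.ndarray
    undefined_pairs: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.matrix.shape == (n, n)
        assert np.allclose(np.diag(self.matrix), 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.matrix[i, j])


@dataclass(frozen=True)
class ClassCall:
    seq_id: str
    class_label: str  # class-1 | class-2 | class-3 | class-4 | unclassified
    basis: str  # architecture | tree | both
    supporting_clade: frozenset = frozenset()


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def identity_matrix(
    aln: AlignmentBlock, region: Optional[tuple[int, int]] = None
) -> DistanceMatrix:
    """Pairwise distance (1 - identity) over the given column range
    (1-based inclusive; default: full alignment).

    Only columns where both rows carry a residue are compared; pairs
    sharing fewer than 10 such columns get an undefined (NaN) distance
    rather than an imputed one.
    """
    lo, hi = region if region is not None else (1, aln.length)
    if not (1 <= lo <= hi <= aln.length):
        raise ValueError(f"region ({lo},{hi}) outside alignment of length {aln.length}")
    ids = aln.ids
    rows = [row[lo - 1 : hi] for _, row in aln.rows]
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in rows]
    nongap = [~np.isin(a, [b"-", b"."]) for a in arrs]
    n = len(ids)
    mat = np.zeros((n, n))
    undefined: set[frozenset] = set()
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            shared = int(both.sum())
            if shared < MIN_SHARED_COLUMNS:
                mat[i, j] = mat[j, i] = np.nan
                undefined.add(frozenset((ids[i], ids[j])))
                continue
            matches = int((arrs[i][both] == arrs[j][both]).sum())
            mat[i, j] = mat[j, i] = 1.0 - matches / shared
    return DistanceMatrix(ids=ids, matrix=mat, undefined_pairs=undefined)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining (Saitou-Nei with the usual Q criterion).

    On additive matrices the induced path metric reproduces the input
    exactly.  Undefined (NaN) entries are an error: remove the offending
    taxa first.
    """
    if np.isnan(dm.matrix).any():
        bad = sorted(sorted(p) for p in dm.undefined_pairs)
        raise ValueError(
            f"distance matrix has undefined entries for pairs {bad}; "
            "remove those taxa before building a tree"
        )
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")
    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = [
        dendropy.Node(taxon=taxa.get_taxon(label)) for label in dm.ids
    ]
    D = dm.matrix.astype(float).copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int) -> None:
        nonlocal D, active, nodes
        i, j = active[i_pos], active[j_pos]
        m = len(active)
        r = D[np.ix_(active, active)].sum(axis=1)
        li = 0.5 * D[i, j] + (r[i_pos] - r[j_pos]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_idx = D.shape[0]
        newrow = np.zeros((1, D.shape[1]))
        D = np.vstack([D, newrow])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic tie-break: smallest (i, j) among minima
        flat = np.argwhere(np.isclose(Q, Q.min(), rtol=0, atol=1e-12))
        i_pos, j_pos = min((min(a, b), max(a, b)) for a, b in flat)
        join(i_pos, j_pos)

    # final star resolution of 3 nodes with exact branch lengths
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.edge.length = length
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_path_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Patristic distance between two leaves (used to verify additivity)."""
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return pdm.distance(ta, tb)


# ---------------------------------------------------------------------------
# Class assignment


def _leaf_labels(node: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def assign_class(
    tree: dendropy.Tree,
    references: dict[str, str],
    query_id: str,
    outgroup: Optional[str] = None,
) -> ClassCall:
    """Assign a class from the smallest clade containing the query and a
    reference.

    The tree is rooted at the user-supplied outgroup leaf if given,
    otherwise at its midpoint.  Walking from the query towards the root,
    the first clade containing any reference decides: a single reference
    class yields that class; a mixed clade leaves the query unclassified
    (the fate of non-metazoan short coronins, which sit outside the
    class-1/class-2 duplication).
    """
    work = tree.clone(depth=1)
    if outgroup is not None:
        node = None
        for lf in work.leaf_node_iter():
            if lf.taxon.label == outgroup:
                node = lf
                break
        if node is None:
            raise KeyError(f"outgroup {outgroup!r} not in tree")
        work.to_outgroup_position(node, update_bipartitions=True)
    else:
        work.reroot_at_midpoint(update_bipartitions=True)
    query_leaf = None
    for lf in work.leaf_node_iter():
        if lf.taxon.label == query_id:
            query_leaf = lf
            break
    if query_leaf is None:
        raise KeyError(f"query {query_id!r} not in tree")
    node = query_leaf.parent_node
    while node is not None:
        clade = _leaf_labels(node)
        ref_classes = {references[l] for l in clade if l in references and l != query_id}
        if ref_classes:
            if len(ref_classes) == 1:
                return ClassCall(
                    seq_id=query_id,
                    class_label=ref_classes.pop(),
                    basis="tree",
                    supporting_clade=clade,
                )
            return ClassCall(
                seq_id=query_id,
                class_label="unclassified",
                basis="tree",
                supporting_clade=clade,
            )
        node = node.parent_node
    raise ValueError("tree contains no reference leaves")


def classify_pipeline(
    record,
    architecture,
    tree: Optional[dendropy.Tree] = None,
    references: Optional[dict[str, str]] = None,
    outgroup: Optional[str] = None,
) -> ClassCall:
    """Combine architecture priors with tree grouping.

    Two coronin-domain hits define class-3; one coronin domain plus any
    villin-derived domain (PH, gelsolin, VHP) defines class-4.  A single
    coronin domain defers to the tree: class-1/class-2 calls come from
    clade grouping (basis 'both' since the short-coronin architecture
    agrees), a tree-supported class-4 without villin domains is accepted
    (bare-domain class-4 members exist), while class-3 without a tandem
    architecture is rejected.  Without tree evidence the sequence stays
    unclassified.
    """
    seq_id = record.id if hasattr(record, "id") else str(record)
    names = [h.domain_name for h in architecture.hits]
    n_coro = names.count("CORO")
    if n_coro >= 2:
        return ClassCall(seq_id, "class-3", "architecture")
    if n_coro >= 1 and any(nm in ("PH", "GEL", "VHP") for nm in names):
        return ClassCall(seq_id, "class-4", "architecture")
    if tree is not None and references:
        try:
            tree_call = assign_class(tree, references, seq_id, outgroup=outgroup)
        except KeyError:
            tree_call = None
        if tree_call is not None:
            label = tree_call.class_label
            if label == "class-3":
                # tandem membership requires the tandem architecture
                return ClassCall(
                    seq_id, "unclassified", "tree", tree_call.supporting_clade
                )
            basis = "both" if label in ("class-1", "class-2") and n_coro == 1 else "tree"
            return ClassCall(seq_id, label, basis, tree_call.supporting_clade)
    return ClassCall(seq_id, "unclassified", "architecture")


# ---------------------------------------------------------------------------
# Sequence logos


@dataclass(frozen=True)
class LogoColumn:
    column: int  # 1-based
    information_content: float  # bits; NaN for all-gap columns
    heights: dict[str, float]  # residue -> freq * IC


def sequence_logo(
    aln: AlignmentBlock,
    region: Optional[tuple[int, int]] = None,
    small_sample_correction: bool = False,
) -> list[LogoColumn]:
    """Per-column information content and letter heights.

    IC(col) = log2(20) - H(col), with H the Shannon entropy of the
    non-gap residue frequencies (X excluded).  Letter height is
    freq * IC, so heights sum to the column's IC.  All-gap columns are
    reported with NaN IC and empty heights.  The optional small-sample
    correction subtracts the classic e_n = 19 / (2 n ln 2) term.
    """
    lo, hi = region if region is not None else (1, aln.length)
    if not (1 <= lo <= hi <= aln.length):
        raise ValueError(f"region ({lo},{hi}) outside alignment of length {aln.length}")
    columns = []
    for col in range(lo, hi + 1):
        counts: dict[str, int] = {}
        for _, row in aln.rows:
            aa = row[col - 1]
            if aa in AA20:
                counts[aa] = counts.get(aa, 0) + 1
        n = sum(counts.values())
        if n == 0:
            columns.append(LogoColumn(col, float("nan"), {}))
            continue
        freqs = {aa: c / n for aa, c in counts.items()}
        entropy = -sum(f * math.log2(f) for f in freqs.values())
        ic = LOG2_20 - entropy
        if small_sample_correction:
            ic -= 19.0 / (2.0 * n * math.log(2.0))
        ic = max(ic, 0.0) if small_sample_correction else ic
        heights = {aa: f * ic for aa, f in sorted(freqs.items())}
        columns.append(LogoColumn(col, ic, heights))
    return columns


def logo_to_json(columns: Sequence[LogoColumn]) -> str:
    import json

    return json.dumps(
        [
            {
                "column": c.column,
                "ic": None if math.isnan(c.information_content) else c.information_content,
                "heights": c.heights,
            }
            for c in columns
        ]
    )
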