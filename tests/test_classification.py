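"""Identity matrices, neighbor joining, clade-based class assignment and
conservation logos."""

import math

import dendropy
import numpy as np
import pytest

from coronin.classification import (
    ClassCall,
    DistanceMatrix,
    assign_class,
    classify_pipeline,
    identity_matrix,
    nj_tree,
    sequence_logo,
    tree_path_distance,
)
from coronin.motif_domain import DomainHit, assemble_architecture
from coronin.seqio import AA20, AlignmentBlock, SequenceRecord, read_tree


class TestIdentityMatrix:
    def test_identical_rows_distance_zero(self):
        aln = AlignmentBlock([("a", "ACDEFGHIKLMN"), ("b", "ACDEFGHIKLMN")])
        assert identity_matrix(aln)[("a", "b")] == 0.0

    def test_half_different(self):
        aln = AlignmentBlock([("a", "AAAAAACCCCCC"), ("b", "AAAAAADDDDDD")])
        dm = identity_matrix(aln)
        assert dm[("a", "b")] == pytest.approx(0.5)

    def test_gap_columns_excluded(self):
        aln = AlignmentBlock([("a", "AAAA-AAAAAAA"), ("b", "AAA-AAAAAAAA")])
        # 10 shared columns, all matching
        assert identity_matrix(aln)[("a", "b")] == 0.0

    def test_too_few_shared_columns_undefined(self):
        aln = AlignmentBlock([("a", "AAAA--------"), ("b", "----AAAAAAAA")])
        dm = identity_matrix(aln)
        assert np.isnan(dm[("a", "b")])
        assert frozenset(("a", "b")) in dm.undefined_pairs

    def test_region_restriction(self):
        aln = AlignmentBlock([("a", "AAAAAAAAAADD"), ("b", "CCCCCCCCCCDD")])
        dm = identity_matrix(aln, region=(1, 10))
        assert dm[("a", "b")] == pytest.approx(1.0)


def random_additive_tree(n_leaves, rng):
    """Random binary tree as nested (child, child, length) tuples plus the
    exact leaf-to-leaf path-length matrix — the oracle for NJ."""
    nodes = [(f"t{i}", 0.0) for i in range(n_leaves)]  # (structure, stem)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(((a, b), float(rng.uniform(0.1, 1.0))))
    root = nodes[0][0]

    dists = {}

    def collect(node, stem):
        # returns {leaf: distance to this node's parent-edge top}
        if isinstance(node, str):
            return {node: stem}
        (a, sa), (b, sb) = node
        da = collect(a, sa)
        db = collect(b, sb)
        for la, xa in da.items():
            for lb, xb in db.items():
                dists[frozenset((la, lb))] = xa + xb
        return {l: d + stem for l, d in {**da, **db}.items()}

    collect(root, 0.0)

    ids = [f"t{i}" for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            D[i, j] = D[j, i] = dists[frozenset((ids[i], ids[j]))]

    def newick(node, stem):
        if isinstance(node, str):
            return f"{node}:{stem}"
        (a, sa), (b, sb) = node
        return f"({newick(a, sa)},{newick(b, sb)}):{stem}"

    nwk = f"({newick(root[0][0], root[0][1])},{newick(root[1][0], root[1][1])});"
    return ids, D, nwk


def rf_distance(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_exact(self):
        # ((A:1,B:2):1,(C:3,D:1)): checked against the four-point condition
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = nj_tree(DistanceMatrix(ids, D))
        for i, a in enumerate(ids):
            for j in range(i + 1, 4):
                assert tree_path_distance(tree, a, ids[j]) == pytest.approx(D[i, j])
        assert rf_distance(
            tree.as_string(schema="newick"), "((A:1,B:2):1,(C:3,D:1));"
        ) == 0

    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = nj_tree(DistanceMatrix(ids, D))
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 3.0, "C": 5.0})

    def test_ultrametric_matches_upgma_topology(self):
        # oracle: scipy average-linkage clustering on the same matrix
        from scipy.cluster.hierarchy import average, to_tree
        from scipy.spatial.distance import squareform

        ids = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], float
        )
        tree = nj_tree(DistanceMatrix(ids, D))

        def upgma_newick(node):
            if node.is_leaf():
                return ids[node.id]
            return f"({upgma_newick(node.left)},{upgma_newick(node.right)})"

        root = to_tree(average(squareform(D)))
        assert rf_distance(tree.as_string(schema="newick"), upgma_newick(root) + ";") == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        ids, D, true_newick = random_additive_tree(n, rng)
        tree = nj_tree(DistanceMatrix(ids, D))
        assert rf_distance(tree.as_string(schema="newick"), true_newick) == 0
        for i in range(n):
            for j in range(i + 1, n):
                assert tree_path_distance(tree, ids[i], ids[j]) == pytest.approx(
                    D[i, j]
                )

    def test_agrees_with_skbio(self):
        import skbio

        rng = np.random.default_rng(7)
        ids, D, _ = random_additive_tree(6, rng)
        ours = nj_tree(DistanceMatrix(ids, D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        assert rf_distance(
            ours.as_string(schema="newick"), str(theirs).strip()
        ) == 0

    def test_undefined_entries_error(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        dm = DistanceMatrix(["a", "b", "c"], D, {frozenset(("a", "b"))})
        with pytest.raises(ValueError, match="remove"):
            nj_tree(dm)


REF_TREE = (
    "(((q1:0.1,(ref1a:0.1,ref1b:0.1):0.1):0.2,"
    "(q2:0.1,(ref2a:0.1,ref2b:0.1):0.1):0.2):0.2,"
    "(orphan:0.4,out3_Cd:0.6):0.1,(ref4:0.9,out4:0.9):0.3);"
)
REFS = {
    "ref1a": "class-1", "ref1b": "class-1",
    "ref2a": "class-2", "ref2b": "class-2",
    "out3_Cd": "class-3", "ref4": "class-4",
}


class TestAssignClass:
    def test_query_sister_to_single_class_clade(self):
        tree = read_tree(REF_TREE)
        call = assign_class(tree, REFS, "q1")
        assert call.class_label == "class-1"
        assert "ref1a" in call.supporting_clade

    def test_mixed_smallest_clade_is_unclassified(self):
        tree = read_tree(REF_TREE)
        call = assign_class(tree, REFS, "orphan", outgroup="out4")
        # walking up from the orphan reaches class-3 first here; use a tree
        # where the nearest reference-containing clade mixes classes
        mixed = "((orphan:0.3,((q1:0.1,ref1a:0.1):0.1,(q2:0.1,ref2a:0.1):0.1):0.1):0.3,(out3:0.5,out4:0.5):0.2);"
        call = assign_class(
            read_tree(mixed),
            {"ref1a": "class-1", "ref2a": "class-2", "out4": "class-4"},
            "orphan",
            outgroup="out4",
        )
        assert call.class_label == "unclassified"

    def test_tandem_second_domain_groups_with_class3(self):
        tree = read_tree(REF_TREE)
        call = assign_class(tree, REFS, "orphan")
        # orphan's sister is the class-3 C-terminal domain reference
        assert call.class_label == "class-3"

    def test_invariant_to_leaf_order(self):
        reordered = (
            "((ref4:0.9,out4:0.9):0.3,(out3_Cd:0.6,orphan:0.4):0.1,"
            "(((ref2b:0.1,ref2a:0.1):0.1,q2:0.1):0.2,"
            "((ref1b:0.1,ref1a:0.1):0.1,q1:0.1):0.2):0.2);"
        )
        a = assign_class(read_tree(REF_TREE), REFS, "q2", outgroup="out4")
        b = assign_class(read_tree(reordered), REFS, "q2", outgroup="out4")
        assert a.class_label == b.class_label == "class-2"

    def test_query_absent_is_error(self):
        with pytest.raises(KeyError):
            assign_class(read_tree(REF_TREE), REFS, "nope")


class TestClassifyPipeline:
    def _record(self, seq_id="q1"):
        return SequenceRecord(id=seq_id, protein="M" * 500)

    def _arch(self, names):
        pos, hits = 1, []
        for n in names:
            hits.append(DomainHit("q1", n, pos, pos + 100, 10.0, "annotation"))
            pos += 120
        return assemble_architecture("q1", hits)

    def test_tandem_architecture_is_class3_without_tree(self):
        call = classify_pipeline(self._record(), self._arch(["CORO", "CORO"]))
        assert (call.class_label, call.basis) == ("class-3", "architecture")

    def test_villin_domains_are_class4(self):
        call = classify_pipeline(
            self._record(), self._arch(["CORO", "PH", "GEL", "VHP"])
        )
        assert (call.class_label, call.basis) == ("class-4", "architecture")

    def test_single_coro_defers_to_tree(self):
        call = classify_pipeline(
            self._record("q1"),
            self._arch(["CORO", "CC"]),
            tree=read_tree(REF_TREE),
            references=REFS,
        )
        assert (call.class_label, call.basis) == ("class-1", "both")

    def test_mixed_clade_stays_unclassified(self):
        mixed = "((q1:0.3,(ref1a:0.2,ref2a:0.2):0.1):0.3,(o1:0.5,out4:0.5):0.2);"
        call = classify_pipeline(
            self._record("q1"),
            self._arch(["CORO", "CC"]),
            tree=read_tree(mixed),
            references={"ref1a": "class-1", "ref2a": "class-2", "out4": "class-4"},
            outgroup="out4",
        )
        assert call.class_label == "unclassified"

    def test_no_tree_single_coro_unclassified(self):
        call = classify_pipeline(self._record(), self._arch(["CORO", "CC"]))
        assert call.class_label == "unclassified"


class TestSequenceLogo:
    def test_invariant_column_full_information(self):
        aln = AlignmentBlock([(f"r{i}", "R") for i in range(10)])
        (col,) = sequence_logo(aln)
        assert col.information_content == pytest.approx(math.log2(20), abs=1e-9)
        assert col.heights["R"] == pytest.approx(math.log2(20), abs=1e-9)

    def test_uniform_column_zero_information(self):
        aln = AlignmentBlock([(f"r{i}", aa) for i, aa in enumerate(AA20)])
        (col,) = sequence_logo(aln)
        assert col.information_content == pytest.approx(0.0, abs=1e-9)

    def test_half_half_column(self):
        aln = AlignmentBlock(
            [(f"r{i}", "R") for i in range(5)] + [(f"k{i}", "K") for i in range(5)]
        )
        (col,) = sequence_logo(aln)
        assert col.information_content == pytest.approx(math.log2(20) - 1, abs=1e-9)

    def test_all_gap_column_reported_missing(self):
        aln = AlignmentBlock([("a", "R-"), ("b", "R-")])
        cols = sequence_logo(aln)
        assert math.isnan(cols[1].information_content)
        assert cols[1].heights == {}

    def test_heights_sum_to_ic_and_range(self, noise_free_family):
        cols = sequence_logo(noise_free_family.domain_alignment)
        for col in cols:
            ic = col.information_content
            assert 0.0 <= ic <= math.log2(20) + 1e-12
            assert sum(col.heights.values()) == pytest.approx(ic)
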