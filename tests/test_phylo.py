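"""K2P distances, UPGMA construction, bootstrap supports, Newick output."""

import math

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average
from scipy.spatial.distance import squareform

from breeddiff import phylo
from breeddiff.phylo import (
    DistanceMatrix,
    SaturationError,
    bootstrap_upgma,
    k2p_distance,
    k2p_matrix,
    to_newick,
    upgma,
)

from conftest import make_alignment


class TestK2P:
    def test_identical_sequences_distance_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_pure_transitions(self):
        s1 = "A" * 100
        s2 = "G" * 10 + "A" * 90  # P = 0.1, Q = 0
        expected = -0.5 * math.log(0.8)
        assert k2p_distance(s1, s2) == pytest.approx(expected, abs=1e-9)
        assert k2p_distance(s1, s2) == pytest.approx(0.111572, abs=5e-7)

    def test_transversions_enter_q_term(self):
        s1 = "A" * 100
        s2 = "C" * 10 + "A" * 90  # P = 0, Q = 0.1
        expected = -0.5 * math.log(0.9 * math.sqrt(0.8))
        assert k2p_distance(s1, s2) == pytest.approx(expected, abs=1e-12)

    def test_saturation_raises(self):
        s1 = "A" * 10
        s2 = "G" * 6 + "A" * 4  # P = 0.6 -> 1 - 2P = -0.2
        with pytest.raises(SaturationError):
            k2p_distance(s1, s2)

    def test_ambiguity_codes_pairwise_deleted(self):
        # R/N columns drop; remaining 4 columns have 1 transition
        assert k2p_distance("RNAAAA", "AAGAAA") == pytest.approx(
            k2p_distance("AAAA", "GAAA")
        )

    def test_no_comparable_sites_errors(self):
        with pytest.raises(SaturationError, match="comparable"):
            k2p_distance("RRR", "AAA")

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            s1 = "".join(bases[rng.integers(0, 4, 50)])
            s2 = "".join(bases[rng.integers(0, 4, 50)])
            try:
                assert k2p_distance(s1, s2) == k2p_distance(s2, s1)
            except SaturationError:
                pass

    def test_reduces_to_p_distance_for_rare_changes(self):
        n = 10_000
        s1 = "A" * n
        s2 = "G" + "A" * (n - 1)
        p = 1.0 / n
        d = k2p_distance(s1, s2)
        assert abs(d - p) / p < 0.01


class TestUpgma:
    def test_two_leaves(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = upgma(dm)
        assert tree.height == pytest.approx(0.2)
        assert tree.leaves() == frozenset({"A", "B"})
        for child in tree.children:
            assert child.height == 0.0

    def test_three_leaf_hand_case(self):
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        tree = upgma(DistanceMatrix(("A", "B", "C"), d))
        assert tree.height == pytest.approx(0.3)
        assert {frozenset({"A", "B"}), frozenset({"A", "B", "C"})} == tree.clades()
        inner = next(c for c in tree.children if not c.is_leaf)
        assert inner.height == pytest.approx(0.1)

    def test_equal_distances_tie_break_deterministic(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(("A", "B", "C", "D"), d)
        newicks = {to_newick(upgma(dm)) for _ in range(5)}
        assert len(newicks) == 1
        # smallest (row, column) pair merges first: (A,B)
        assert frozenset({"A", "B"}) in upgma(dm).clades()

    def test_recovers_random_ultrametric_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            labels, dist, true_clades, true_heights = _random_ultrametric(rng)
            tree = upgma(DistanceMatrix(tuple(labels), dist))
            assert tree.clades() == true_clades
            got = {
                node.leaves(): node.height
                for node in tree.walk()
                if not node.is_leaf
            }
            for clade, h in true_heights.items():
                assert got[clade] == pytest.approx(h, abs=1e-9)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(9)
        d = squareform(rng.uniform(0.1, 1.0, size=15))
        tree = upgma(DistanceMatrix(tuple("ABCDEF"), d))
        depths = _leaf_depths(tree)
        assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            condensed = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
            tree = upgma(DistanceMatrix(
                tuple(f"t{k}" for k in range(n)), squareform(condensed)
            ))
            ours = sorted(
                node.height for node in tree.walk() if not node.is_leaf
            )
            theirs = sorted(scipy_average(condensed)[:, 2] / 2.0)
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestBootstrap:
    def split_alignment(self, n_fixed=10, n_const=90):
        seq_a = "A" * n_fixed + "A" * n_const
        seq_b = "G" * n_fixed + "A" * n_const
        return make_alignment(
            {f"x{k}": seq_a for k in range(3)} | {f"y{k}": seq_b for k in range(3)}
        )

    def test_clear_split_gets_full_support(self):
        aln = self.split_alignment()
        tree, discarded = bootstrap_upgma(aln, B=100, seed=1)
        assert discarded == 0
        supports = {n.leaves(): n.support for n in tree.walk() if not n.is_leaf}
        assert supports[frozenset({"x0", "x1", "x2"})] == 100.0
        assert supports[frozenset({"y0", "y1", "y2"})] == 100.0

    def test_single_replicate_supports_binary(self):
        aln = self.split_alignment()
        tree, _ = bootstrap_upgma(aln, B=1, seed=5)
        for node in tree.walk():
            if not node.is_leaf:
                assert node.support in (0.0, 100.0)

    def test_same_seed_same_supports(self):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGT"))
        root = bases[rng.integers(0, 4, 60)]
        seqs = {}
        for k in range(5):  # each sample: root + a few substitutions
            s = root.copy()
            for pos in rng.integers(0, 60, size=4):
                s[pos] = bases[rng.integers(0, 4)]
            seqs[f"s{k}"] = "".join(s)
        aln = make_alignment(seqs)
        t1, _ = bootstrap_upgma(aln, B=50, seed=99)
        t2, _ = bootstrap_upgma(aln, B=50, seed=99)
        assert to_newick(t1) == to_newick(t2)

    def test_invalid_b(self):
        with pytest.raises(ValueError):
            bootstrap_upgma(self.split_alignment(), B=0, seed=1)


class TestNewick:
    def test_roundtrip_through_dendropy(self):
        rng = np.random.default_rng(8)
        d = squareform(rng.uniform(0.1, 1.0, size=10))
        tree = upgma(DistanceMatrix(tuple("ABCDE"), d))
        for node in tree.walk():
            if not node.is_leaf:
                node.support = float(rng.integers(0, 101))
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick",
                                   suppress_internal_node_taxa=True)
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set("ABCDE")
        # ultrametric depths preserved
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in parsed.leaf_node_iter()
        }
        assert max(depths.values()) == pytest.approx(tree.height, abs=1e-9)
        assert min(depths.values()) == pytest.approx(tree.height, abs=1e-9)
        # supports stored as internal labels
        labels = {
            int(n.label) for n in parsed.preorder_internal_node_iter()
            if n.label is not None
        }
        expected = {
            int(round(n.support)) for n in tree.walk() if not n.is_leaf
        }
        assert labels <= expected

    def test_k2p_matrix_on_alignment(self):
        aln = make_alignment({"a": "AAAA", "b": "GAAA", "c": "AAAA"})
        dm = k2p_matrix(aln)
        assert dm.d[0, 2] == 0.0
        assert dm.d[0, 1] == pytest.approx(k2p_distance("AAAA", "GAAA"))


def _leaf_depths(tree):
    depths = {}

    def walk(node, acc):
        if node.is_leaf:
            depths[node.label] = acc
        for child in node.children:
            walk(child, acc + (node.height - child.height))

    walk(tree, 0.0)
    return depths


def _random_ultrametric(rng):
    """Random ultrametric tree -> (labels, distance matrix, clades, heights)."""
    n = int(rng.integers(3, 9))
    labels = [f"t{k}" for k in range(n)]
    clusters = [(frozenset([lab]), 0.0) for lab in labels]
    clades = set()
    heights = {}
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(0.05, 0.3))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = clusters[i][0] | clusters[j][0]
        clades.add(merged)
        heights[merged] = height
        clusters[i] = (merged, height)
        del clusters[j]
    mrca_height = {}
    for clade, h in sorted(heights.items(), key=lambda kv: kv[1], reverse=True):
        for a in clade:
            for b in clade:
                if a != b:
                    mrca_height[(a, b)] = h
    dist = np.zeros((n, n))
    for ia, a in enumerate(labels):
        for ib, b in enumerate(labels):
            if a != b:
                dist[ia, ib] = 2.0 * mrca_height[(a, b)]
    return labels, dist, clades, heights
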