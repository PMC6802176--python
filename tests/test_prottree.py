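"""Proteomic tree: Dice distance, distance matrices, NJ, consensus."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakephage.prottree import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    alternative_topologies,
    build_distance_matrix,
    consensus_tree,
    dice_distance,
    neighbor_joining,
)
from lakephage.seqcore import NucleotideSequence
from lakephage.synth import _reverse_translate

from .conftest import random_dna


class TestDiceDistance:
    @pytest.mark.parametrize(
        "ab,aa,bb,expected",
        [(100, 100, 100, 0.0), (0, 100, 300, 1.0), (100, 100, 300, 0.5)],
    )
    def test_arithmetic(self, ab, aa, bb, expected):
        assert dice_distance(ab, aa, bb) == pytest.approx(expected, abs=0)

    @given(
        st.floats(min_value=0, max_value=1000),
        st.floats(min_value=1, max_value=1000),
        st.floats(min_value=1, max_value=1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_symmetry(self, ab, aa, bb):
        d = dice_distance(ab, aa, bb)
        assert 0.0 <= d <= 1.0
        assert d == dice_distance(ab, bb, aa)

    def test_self_distance_zero(self):
        assert dice_distance(250.0, 250.0, 250.0) == 0.0

    def test_zero_self_score_errors(self):
        with pytest.raises(ValueError):
            dice_distance(1.0, 0.0, 10.0)


def _coding_genome(rng, gid, proteins):
    parts = [random_dna(rng, 300)]
    for p in proteins:
        parts.append(_reverse_translate(p))
        parts.append(random_dna(rng, 300))
    return NucleotideSequence(gid, "".join(parts))


class TestBuildDistanceMatrix:
    def test_identical_vs_unrelated(self):
        rng = np.random.default_rng(30)
        prots = ["M" + "".join(rng.choice(list("ARNDCEQGHILKMFPSTWYV"), 150)) for _ in range(4)]
        other = ["M" + "".join(rng.choice(list("ARNDCEQGHILKMFPSTWYV"), 150)) for _ in range(4)]
        g1 = _coding_genome(rng, "g1", prots)
        g2 = NucleotideSequence("g2", g1.residues)
        g3 = _coding_genome(rng, "g3", other)
        matrix = build_distance_matrix([g1, g2, g3])
        assert matrix[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert matrix[0, 2] == pytest.approx(1.0, abs=0.05)
        assert matrix[1, 2] == pytest.approx(matrix[0, 2], abs=1e-9)

    def test_distance_orders_with_shared_protein_fraction(self):
        rng = np.random.default_rng(31)
        alphabet = list("ARNDCEQGHILKMFPSTWYV")
        shared = ["M" + "".join(rng.choice(alphabet, 200)) for _ in range(4)]
        own = [["M" + "".join(rng.choice(alphabet, 200)) for _ in range(4)] for _ in range(3)]
        # g1 shares 2/4 proteins with g0, g2 shares 1/4, g3 shares none
        g0 = _coding_genome(rng, "g0", shared)
        g1 = _coding_genome(rng, "g1", shared[:2] + own[0][:2])
        g2 = _coding_genome(rng, "g2", shared[:1] + own[1][:3])
        g3 = _coding_genome(rng, "g3", own[2])
        matrix = build_distance_matrix([g0, g1, g2, g3])
        assert matrix[0, 1] < matrix[0, 2] < matrix[0, 3]


def _random_additive_tree(rng, n):
    """Random unrooted binary tree over n taxa with random branch lengths;
    returns (distance matrix, set of bipartitions)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    active = list(nodes)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        parent = TreeNode(
            children=[(a, float(rng.uniform(0.05, 0.3))), (b, float(rng.uniform(0.05, 0.3)))]
        )
        active = [x for x in active if x not in (a, b)] + [parent]
    root = TreeNode(children=[(x, float(rng.uniform(0.05, 0.3))) for x in active])
    tree = PhyloTree(root=root)
    # additive distances: sum branch lengths along the path between leaves
    leaf_paths = {}

    def collect(node, edges):
        if node.is_leaf:
            leaf_paths[node.name] = edges
            return
        for child, length in node.children:
            collect(child, edges + [(id(child), length)])

    collect(root, [])
    names = sorted(leaf_paths)
    values = np.zeros((n, n))
    for x, y in itertools.combinations(range(n), 2):
        ex = leaf_paths[names[x]]
        ey = leaf_paths[names[y]]
        shared = 0
        for (ia, la), (ib, lb) in zip(ex, ey):
            if ia == ib:
                shared += 1
            else:
                break
        d = sum(l for _i, l in ex[shared:]) + sum(l for _i, l in ey[shared:])
        values[x, y] = values[y, x] = d
    scale = values.max()
    matrix = DistanceMatrix(ids=names, values=values / (scale * 1.01))
    return matrix, tree.bipartitions()


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        matrix = DistanceMatrix(ids=["a", "b"], values=[[0, 0.4], [0.4, 0]])
        tree = neighbor_joining(matrix)
        assert sorted(tree.root.leaves()) == ["a", "b"]
        assert tree.total_length() == pytest.approx(0.4)

    def test_recovers_known_quartet(self):
        # ((a,b),(c,d)) with internal edge 0.1
        values = np.array(
            [
                [0.0, 0.2, 0.45, 0.5],
                [0.2, 0.0, 0.45, 0.5],
                [0.45, 0.45, 0.0, 0.3],
                [0.5, 0.5, 0.3, 0.0],
            ]
        )
        matrix = DistanceMatrix(ids=["a", "b", "c", "d"], values=values)
        tree = neighbor_joining(matrix)
        assert tree.bipartitions() == {frozenset({"c", "d"})} or tree.bipartitions() == {
            frozenset({"a", "b"})
        }

    def test_recovers_additive_topologies(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            matrix, truth = _random_additive_tree(rng, 8)
            tree = neighbor_joining(matrix)
            assert tree.bipartitions() == truth

    def test_matches_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(34)
        matrix, _truth = _random_additive_tree(rng, 8)
        ours = neighbor_joining(matrix)
        dm = skbio.DistanceMatrix(matrix.values, ids=matrix.ids)
        ref = skbio.tree.nj(dm)
        ref_bips = set()
        n = len(matrix.ids)
        all_ids = set(matrix.ids)
        anchor = min(all_ids)
        for node in ref.non_tips():
            clade = {t.name for t in node.tips()}
            side = all_ids - clade if anchor in clade else clade
            if 2 <= len(side) <= n - 2:
                ref_bips.add(frozenset(side))
        assert ours.bipartitions() == ref_bips

    def test_seeded_alternatives_share_leaf_set(self):
        rng = np.random.default_rng(35)
        matrix, _ = _random_additive_tree(rng, 8)
        trees = alternative_topologies(matrix, n_trees=10, seed=3)
        assert len(trees) == 10
        assert all(t.leaf_names() == trees[0].leaf_names() for t in trees)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], values=[[0, 0.5], [0.4, 0]])


def _tree_from_bipartition(leaves, inner):
    """Binary-ish tree over ``leaves`` containing the clade ``inner``."""
    inner_nodes = [TreeNode(name=x) for x in sorted(inner)]
    rest = [TreeNode(name=x) for x in sorted(set(leaves) - set(inner))]
    clade = TreeNode(children=[(x, 0.1) for x in inner_nodes])
    return PhyloTree(root=TreeNode(children=[(clade, 0.1)] + [(x, 0.1) for x in rest]))


class TestConsensusTree:
    def test_identical_trees_full_support(self):
        rng = np.random.default_rng(36)
        matrix, _ = _random_additive_tree(rng, 6)
        tree = neighbor_joining(matrix)
        cons = consensus_tree([tree] * 100)
        assert cons.bipartitions() == tree.bipartitions()
        for node, _len in _iter_internal(cons):
            assert node.support == pytest.approx(1.0)

    def test_partial_support_counted_directly(self):
        leaves = ["a", "b", "c", "d", "e"]
        with_x = _tree_from_bipartition(leaves, {"d", "e"})
        without_x = PhyloTree(
            root=TreeNode(children=[(TreeNode(name=x), 0.1) for x in leaves])
        )
        cons = consensus_tree([with_x] * 60 + [without_x] * 40)
        assert cons.bipartitions() == {frozenset({"d", "e"})}
        supports = [n.support for n, _l in _iter_internal(cons)]
        assert supports == [pytest.approx(0.6)]

    def test_conflicting_trees_collapse_to_star(self):
        leaves = ["a", "b", "c", "d"]
        t1 = _tree_from_bipartition(leaves, {"c", "d"})
        t2 = _tree_from_bipartition(leaves, {"b", "d"})
        cons = consensus_tree([t1, t2])
        assert cons.bipartitions() == set()

    def test_mismatched_leaf_sets_rejected(self):
        t1 = _tree_from_bipartition(["a", "b", "c", "d"], {"c", "d"})
        t2 = _tree_from_bipartition(["a", "b", "c", "e"], {"c", "e"})
        with pytest.raises(ValueError):
            consensus_tree([t1, t2])


def _iter_internal(tree):
    from lakephage.prottree import _walk_edges

    for node, length in _walk_edges(tree.root):
        if not node.is_leaf:
            yield node, length
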