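"""Phage proteomic tree.

Whole-genome phage phylogeny from translated sequence similarity rather than
any single marker gene: an all-vs-all six-frame translated comparison sums
the scores of all significant hits into a comparison score S(A,B); the Dice
coefficient 2*S(A,B) / (S(A,A) + S(B,B)) is turned into a distance
1 - Dice; neighbor joining on the distance matrix gives a topology, and
randomized tie-breaking across many seeded runs yields alternative topologies
whose majority-rule consensus carries per-bipartition support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .discovery import PhageGenome
from .seqcore import AlignerParams, NucleotideSequence, translated_align

# ---------------------------------------------------------------------------
# similarity scores and Dice distance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityScore:
    a_id: str
    b_id: str
    summed_score: float

    def __post_init__(self):
        if self.summed_score < 0:
            raise ValueError("summed score must be >= 0")


def comparison_score(
    a: NucleotideSequence, b: NucleotideSequence, params: AlignerParams | None = None
) -> float:
    """Summed score of all significant translated hits between two genomes."""
    return float(sum(h.score for h in translated_align(a, b, params)))


def dice_distance(score_ab: float, score_aa: float, score_bb: float) -> float:
    """1 - 2*S(A,B)/(S(A,A)+S(B,B)), clamped to [0, 1]."""
    if score_aa <= 0 or score_bb <= 0:
        raise ValueError("self-comparison scores must be positive")
    if score_ab < 0:
        raise ValueError("comparison score must be >= 0")
    coefficient = 2.0 * score_ab / (score_aa + score_bb)
    return float(min(1.0, max(0.0, 1.0 - coefficient)))


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any((self.values < 0) | (self.values > 1.0 + 1e-12)):
            raise ValueError("entries must lie in [0, 1]")

    def __getitem__(self, pair):
        i, j = pair
        return float(self.values[i, j])


def build_distance_matrix(
    genomes: list[PhageGenome] | list[NucleotideSequence],
    params: AlignerParams | None = None,
) -> DistanceMatrix:
    """Dice distance matrix from all-vs-all translated comparisons.

    Each unordered pair is aligned once (the score is symmetric by
    construction); self-comparisons provide the normalizers.
    """
    seqs = [g.sequence if isinstance(g, PhageGenome) else g for g in genomes]
    if params is None:
        params = AlignerParams.translated()
    n = len(seqs)
    ids = [s.id for s in seqs]
    self_scores = np.array([comparison_score(s, s, params) for s in seqs])
    if np.any(self_scores <= 0):
        bad = [ids[i] for i in np.nonzero(self_scores <= 0)[0]]
        raise ValueError(f"zero self-comparison score for {bad} (no ORFs?)")
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        s_ab = comparison_score(seqs[i], seqs[j], params)
        d = dice_distance(s_ab, self_scores[i], self_scores[j])
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary root; supports live on internal
    nodes as the fraction of input trees containing the bipartition."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each normalized to the side *not*
        containing the lexicographically smallest leaf."""
        leaves = set(self.root.leaves())
        anchor = min(leaves)
        n = len(leaves)
        out: set[frozenset[str]] = set()
        for node, _parent_len in _walk_edges(self.root):
            clade = set(node.leaves())
            side = leaves - clade if anchor in clade else clade
            if 2 <= len(side) <= n - 2:
                out.add(frozenset(side))
        return out

    def bipartition_lengths(self) -> dict[frozenset[str], float]:
        leaves = set(self.root.leaves())
        anchor = min(leaves)
        n = len(leaves)
        out: dict[frozenset[str], float] = {}
        for node, parent_len in _walk_edges(self.root):
            clade = set(node.leaves())
            side = leaves - clade if anchor in clade else clade
            if 2 <= len(side) <= n - 2:
                out[frozenset(side)] = out.get(frozenset(side), 0.0) + parent_len
        return out

    def newick(self, with_support: bool = False) -> str:
        return _newick(self.root, with_support) + ";"

    def total_length(self) -> float:
        return sum(length for _node, length in _walk_edges(self.root))


def _walk_edges(root: TreeNode):
    """Yield (child, branch_length) for every edge below ``root``."""
    stack = [root]
    while stack:
        node = stack.pop()
        for child, length in node.children:
            yield child, length
            stack.append(child)


def _newick(node: TreeNode, with_support: bool) -> str:
    if node.is_leaf:
        return node.name
    inner = ",".join(
        f"{_newick(child, with_support)}:{length:.6f}" for child, length in node.children
    )
    label = ""
    if with_support and node.support is not None:
        label = f"{node.support:.3f}"
    return f"({inner}){label}"


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(
    matrix: DistanceMatrix,
    seed: int | None = None,
    epsilon: float | None = None,
) -> PhyloTree:
    """Canonical neighbor joining with optional randomized tie handling.

    With ``seed`` given, each join is drawn uniformly among the pairs whose
    Q-criterion lies within ``epsilon`` of the minimum, and the leaf order is
    randomly permuted first — repeated seeded runs generate alternative,
    equally valid topologies.  With ``seed=None`` the procedure is fully
    deterministic (first minimal pair in row-major order).  Negative branch
    lengths are clamped to zero.
    """
    ids = list(matrix.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two taxa")
    d = matrix.values.astype(float).copy()
    if epsilon is None:
        epsilon = 1e-9 * max(float(d.max()), 1.0)
    rng = np.random.default_rng(seed) if seed is not None else None
    order = list(range(n))
    if rng is not None:
        rng.shuffle(order)
        d = d[np.ix_(order, order)]
        ids = [ids[i] for i in order]
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + epsilon)
        cand = cand[cand[:, 0] < cand[:, 1]]
        if rng is not None and len(cand) > 1:
            pick = cand[rng.integers(len(cand))]
        else:
            pick = cand[0]
        i, j = int(pick[0]), int(pick[1])
        gi, gj = active[i], active[j]
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = TreeNode(children=[(nodes[gi], vi), (nodes[gj], vj)])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        g_new = d.shape[0] - 1
        active = [g for g in active if g not in (gi, gj)] + [g_new]
    if len(active) == 2:
        gi, gj = active
        dij = max(float(d[gi, gj]), 0.0)
        if nodes[gi].is_leaf and nodes[gj].is_leaf:
            root = TreeNode(children=[(nodes[gi], dij / 2.0), (nodes[gj], dij / 2.0)])
        elif nodes[gj].is_leaf:
            nodes[gi].children.append((nodes[gj], dij))
            root = nodes[gi]
        else:
            nodes[gj].children.append((nodes[gi], dij))
            root = nodes[gj]
    else:  # single taxon
        root = nodes[active[0]]
    return PhyloTree(root=root)


def alternative_topologies(
    matrix: DistanceMatrix,
    n_trees: int = 100,
    seed: int = 0,
    epsilon: float | None = None,
) -> list[PhyloTree]:
    """Seeded family of equally valid NJ topologies (tie-broken randomly)."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_trees)
    return [neighbor_joining(matrix, seed=int(s), epsilon=epsilon) for s in child_seeds]


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def consensus_tree(trees: list[PhyloTree], min_frequency: float = 0.5) -> PhyloTree:
    """Majority-rule consensus (bipartitions in strictly more than half of the
    input trees; strict majority sets are mutually compatible).

    Support on each retained internal node is the fraction of trees carrying
    the bipartition; branch lengths average over those trees.  Terminal branch
    lengths average over all trees.
    """
    if not trees:
        raise ValueError("need at least one tree")
    leaf_sets = {frozenset(t.root.leaves()) for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("trees must share one leaf set")
    leaves = sorted(next(iter(leaf_sets)))
    anchor = leaves[0]
    t_count = len(trees)
    counts: dict[frozenset[str], int] = {}
    lengths: dict[frozenset[str], float] = {}
    term_lengths = {leaf: 0.0 for leaf in leaves}
    for tree in trees:
        for bip, length in tree.bipartition_lengths().items():
            counts[bip] = counts.get(bip, 0) + 1
            lengths[bip] = lengths.get(bip, 0.0) + length
        for node, length in _walk_edges(tree.root):
            if node.is_leaf:
                term_lengths[node.name] += length
    majority = {bip: c for bip, c in counts.items() if c / t_count > min_frequency}
    # build rooted-at-anchor clade structure: each bipartition side excludes
    # the anchor, so the retained sides form a laminar family of clades
    clades = sorted(majority, key=len, reverse=True)
    leaf_nodes = {leaf: TreeNode(name=leaf) for leaf in leaves}
    root = TreeNode()
    clade_nodes: list[tuple[frozenset[str], TreeNode]] = []
    parent_of: dict[int, TreeNode] = {}

    def _find_parent(members: frozenset[str]) -> TreeNode:
        for cl, node in reversed(clade_nodes):
            if members <= cl:
                return node
        return root

    for bip in clades:
        node = TreeNode(support=counts[bip] / t_count)
        parent = _find_parent(bip)
        parent.children.append((node, lengths[bip] / counts[bip]))
        clade_nodes.append((bip, node))
    for leaf in leaves:
        parent = _find_parent(frozenset([leaf]))
        parent.children.append((leaf_nodes[leaf], term_lengths[leaf] / t_count))
    return PhyloTree(root=root)
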