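"""Tree-based per-position conservation levels.

A site is conserved when it segregates cleanly along the evolutionary tree
of the aligned sequences: there exist at least two anciently diverged
subtrees, each internally homogeneous at that site (all its sequences
display the same amino acid).  The tree is built from global pairwise
similarities, so the whole sequence context enters every per-site level.

Concretely, the tree is an average-linkage hierarchy on the normalized
Hamming distance matrix.  For a site *i* we scan merge heights from the
root downward; at each height the broken merges induce a partition into
subtrees, and the site's conservation is h*/h_root, where h* is the
greatest height at which at least two subtrees of size >= m_min are each
homogeneous at *i* (gap symbols are ignored when testing homogeneity, but a
subtree that is all-gap at *i* carries no evidence and does not qualify).
A column whose rows all display one identical residue scores 1; a column in
which no level qualifies scores 0.  m_min defaults to max(2, ceil(0.05 N)).

"Ancient origin" has no quantitative definition in the literature this
follows; the height-fraction scan above is this module's operational
definition (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .msa_io import Alignment, GAP
from .depth_metrics import pairwise_hamming


@dataclass
class SequenceTree:
    """Rooted hierarchy over the N sequences of an alignment.

    ``linkage`` is the (N-1) x 4 merge table; ``heights`` its merge
    distances, non-decreasing from leaves to root.  Leaf ``i`` of the
    linkage corresponds to alignment row ``leaf_order[i]``: rows are sorted
    lexicographically before clustering so that distance ties are broken by
    sequence content, never by input order, and the tree (hence every
    conservation level) is invariant under row permutation.
    """

    linkage: np.ndarray
    n_leaves: int
    leaf_order: np.ndarray | None = None
    method: str = "average"

    def __post_init__(self) -> None:
        if self.leaf_order is None:
            self.leaf_order = np.arange(self.n_leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def root_height(self) -> float:
        return float(self.heights[-1]) if len(self.linkage) else 0.0

    def newick(self, labels: list[str] | None = None) -> str:
        """Serialize as a Newick string with merge-height branch lengths."""
        if labels is None:
            labels = [f"seq{i}" for i in range(self.n_leaves)]
        if not len(self.linkage):
            return f"{labels[0]};"
        tree = hierarchy.to_tree(self.linkage)
        order = self.leaf_order

        def fmt(node, parent_height):
            bl = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[order[node.id]]}:{bl:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{bl:.6g}"

        return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"


@dataclass
class ConservationProfile:
    levels: np.ndarray
    tree: SequenceTree
    m_min: int
    linkage_method: str = "average"

    def __len__(self) -> int:
        return len(self.levels)


def build_tree(aln: Alignment, method: str = "average") -> SequenceTree:
    """Agglomerative tree on the normalized Hamming distance matrix.

    Average linkage by default.  Rows are ordered lexicographically before
    clustering, so exact distance ties (common, since distances are
    multiples of 1/L) resolve by sequence content and the tree does not
    depend on input row order.  A single-sequence alignment yields a
    degenerate one-leaf tree.
    """
    if aln.n == 1:
        return SequenceTree(linkage=np.empty((0, 4)), n_leaves=1, method=method)
    order = np.array(sorted(range(aln.n), key=lambda s: aln.row(s)))
    dmat = pairwise_hamming(aln)[np.ix_(order, order)]
    condensed = squareform(dmat, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return SequenceTree(linkage=Z, n_leaves=aln.n, leaf_order=order, method=method)


def default_m_min(n: int) -> int:
    """Minimum subtree size admitted as homogeneity evidence:
    max(2, ceil(0.025 N)).

    A singleton leaf is trivially homogeneous and carries no segregation
    signal, so subtrees must hold at least two sequences; scaling the gate
    mildly with N discounts accidental sister-pair homogeneity in large
    alignments.  Much larger gates are counterproductive: requiring two
    perfectly homogeneous clades of, say, 5% of N zeroes out most
    moderately constrained sites (a single homoplasy anywhere in a large
    clade breaks strict homogeneity), flattening the profile instead of
    grading it.
    """
    return max(2, int(np.ceil(0.025 * n)))


def _level_partitions(tree: SequenceTree) -> list[tuple[float, list[np.ndarray]]]:
    """Partitions induced by breaking merges from the root downward.

    Returns (height, clusters) pairs in decreasing height order, where
    ``height`` is the merge height being broken and ``clusters`` the leaf
    index sets of the resulting subtrees.  The first entry is the root's
    two children at the root height.
    """
    Z = tree.linkage
    n = tree.n_leaves
    # leaf sets per internal node, built bottom-up
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    for a, b, _h, _c in Z:
        members.append(np.concatenate([members[int(a)], members[int(b)]]))

    heights = Z[:, 2]
    parent_of: dict[int, int] = {}
    for m, (a, b, _hh, _c) in enumerate(Z):
        parent_of[int(a)] = n + m
        parent_of[int(b)] = n + m

    out: list[tuple[float, list[np.ndarray]]] = []
    # break ties together: all merges at the same height are undone at once
    distinct = np.unique(heights)[::-1]
    for h in distinct:
        keep = heights < h
        # active clusters: nodes not merged below h whose parents merge at >= h
        active = []
        for node in range(n + len(Z)):
            merged_below = node >= n and not keep[node - n]
            if merged_below:
                continue
            parent = parent_of.get(node)
            if parent is None or not keep[parent - n]:
                active.append(members[node])
        out.append((float(h), active))
    return out


def _column_levels(
    column: np.ndarray,
    partitions: list[tuple[float, list[np.ndarray]]],
    root_height: float,
    m_min: int,
) -> float:
    non_gap = column != GAP
    if not non_gap.any():
        return 0.0
    residues = column[non_gap]
    if np.all(residues == residues[0]) and non_gap.all():
        return 1.0  # fully conserved column
    for h, clusters in partitions:
        qualifying = 0
        for leaves in clusters:
            if len(leaves) < m_min:
                continue
            sub = column[leaves]
            sub = sub[sub != GAP]
            if len(sub) and np.all(sub == sub[0]):
                qualifying += 1
                if qualifying >= 2:
                    break
        if qualifying >= 2:
            return h / root_height if root_height > 0 else 1.0
    return 0.0


def position_conservation(
    aln: Alignment,
    tree: SequenceTree,
    i: int,
    m_min: int | None = None,
) -> float:
    """Conservation level of 0-based query position ``i`` in [0, 1]."""
    if not 0 <= i < aln.L:
        raise IndexError(f"position {i} outside [0, {aln.L})")
    if aln.n == 1:
        return 1.0
    if m_min is None:
        m_min = default_m_min(aln.n)
    if tree.root_height == 0.0:
        # all rows identical: every position fully conserved
        return 1.0
    partitions = _level_partitions(tree)
    column = aln.matrix[tree.leaf_order, i]
    return _column_levels(column, partitions, tree.root_height, m_min)


def conservation_profile(
    aln: Alignment,
    tree: SequenceTree | None = None,
    m_min: int | None = None,
    method: str = "average",
) -> ConservationProfile:
    """Per-position conservation levels over one shared tree."""
    if tree is None:
        tree = build_tree(aln, method=method)
    if m_min is None:
        m_min = default_m_min(aln.n)
    if aln.n == 1 or tree.root_height == 0.0:
        levels = np.ones(aln.L)
    else:
        partitions = _level_partitions(tree)
        sorted_matrix = aln.matrix[tree.leaf_order]
        levels = np.array(
            [
                _column_levels(sorted_matrix[:, i], partitions, tree.root_height, m_min)
                for i in range(aln.L)
            ]
        )
    return ConservationProfile(
        levels=levels, tree=tree, m_min=m_min, linkage_method=tree.method
    )
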