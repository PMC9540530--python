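"""Faith's phylogenetic diversity over ensembles of dated trees.

Faith's PD for a species set is the sum of branch lengths of the minimum
spanning subtree connecting the corresponding tips.  We use the
root-excluded convention: the subtree is rooted at the most recent
common ancestor (MRCA) of the selected tips, so branches between that
ancestor and the tree root do not contribute, and a single tip has
PD = 0.

Dated trees come with phylogenetic uncertainty, so PD is evaluated over
an ensemble of trees sharing one tip set.  Each tree's PD is rescaled by
that tree's total branch length (so the full tip set scores 1 on a tree
without a root edge) and the rescaled values are averaged across trees.
Rescaling per tree before averaging keeps the statistic invariant to a
uniform rescaling of any single tree's branch lengths; averaging raw PD
first and dividing by the mean total length is also exposed for
comparison but is not the default.

Trees are parsed with dendropy and then encoded into flat arrays
(parent pointers plus a tip-by-edge incidence matrix) so that PD for
many species sets over many trees reduces to boolean matrix products.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloTreeEnsemble",
    "faith_pd",
    "total_branch_length",
    "scaled_pd",
    "read_newick_trees",
    "parse_newick",
]


@dataclass
class PhyloTree:
    """A rooted tree encoded for fast spanning-subtree sums.

    Nodes are indexed 0..n_nodes-1 with tips first (in ``tip_labels``
    order).  ``edge_lengths[i]`` is the length of the branch above node
    ``i`` (0 for the root when the Newick carries no root edge).
    ``tip_incidence[t, i]`` is True when tip ``t`` lies below the branch
    above node ``i``.
    """

    tip_labels: tuple[str, ...]
    parent: np.ndarray  # int, -1 for root
    edge_lengths: np.ndarray  # float, per node
    tip_incidence: np.ndarray  # bool, (n_tips, n_nodes)

    def __post_init__(self) -> None:
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        if len(self._tip_index) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        if np.any(self.edge_lengths < 0):
            raise ValueError("branch lengths must be non-negative")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_mask(self, tips) -> np.ndarray:
        mask = np.zeros(self.n_tips, dtype=bool)
        for t in tips:
            try:
                mask[self._tip_index[t]] = True
            except KeyError:
                raise KeyError(f"tip {t!r} not in tree") from None
        return mask

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        tree = tree.clone(depth=1)
        if not tree.is_rooted:
            tree.is_rooted = True
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = []
        for lf in leaves:
            if lf.taxon is None or not lf.taxon.label:
                raise ValueError("tree contains an unlabelled tip")
            labels.append(lf.taxon.label)
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        order = leaves + internals
        index = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n, dtype=float)
        for nd in order:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is not None:
                lengths[i] = float(nd.edge.length)
        incidence = np.zeros((len(leaves), n), dtype=bool)
        for t, lf in enumerate(leaves):
            nd = lf
            while nd is not None:
                incidence[t, index[id(nd)]] = True
                nd = nd.parent_node
        return cls(tuple(labels), parent, lengths, incidence)


@dataclass
class PhyloTreeEnsemble:
    """An ordered list of trees over one shared tip set."""

    trees: list[PhyloTree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("ensemble must contain at least one tree")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], start=2):
            if set(t.tip_labels) != ref:
                raise ValueError(f"tree {i} has a different tip set")

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(self.trees[0].tip_labels)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def faith_pd(tree: PhyloTree, tips, include_root: bool = False) -> float:
    """Sum of branch lengths of the minimal subtree spanning ``tips``.

    By default root-excluded: branches between the tips' MRCA and the
    tree root are not counted, and sets of zero or one tip score 0.
    With ``include_root=True`` the subtree is extended to the tree root
    (the convention under which PD is subadditive over arbitrary unions).
    """
    mask = tree.tip_mask(tips)
    k = int(mask.sum())
    if k == 0 or (k == 1 and not include_root):
        return 0.0
    # selected tips below each branch (cast: bool matmul would OR, not count)
    counts = mask.astype(np.int64) @ tree.tip_incidence.astype(np.int64)
    if include_root:
        on = counts >= 1
    else:
        # A branch is in the root-excluded spanning subtree iff it has at
        # least one selected tip below it but not all of them (branches with
        # all k below are the MRCA's stem and everything rootward of it).
        on = (counts >= 1) & (counts < k)
    return float(tree.edge_lengths[on].sum())


def total_branch_length(tree: PhyloTree) -> float:
    """Sum over every branch in the tree (root edge included if present)."""
    return float(tree.edge_lengths.sum())


def scaled_pd(
    ensemble: PhyloTreeEnsemble, tips, per_tree: bool = True
) -> tuple[float, float]:
    """Ensemble-mean rescaled PD with its across-tree standard deviation.

    With ``per_tree=True`` (default) each tree's PD is divided by that
    tree's total branch length before averaging; otherwise raw PD values
    are averaged and divided by the mean total branch length.
    """
    tips = set(tips)
    unknown = tips - ensemble.tip_labels
    if unknown:
        raise KeyError(f"tips not in trees: {sorted(unknown)}")
    pds = np.empty(len(ensemble))
    totals = np.empty(len(ensemble))
    for i, tree in enumerate(ensemble):
        totals[i] = total_branch_length(tree)
        if totals[i] <= 0:
            raise ValueError(f"tree {i + 1} has zero total branch length")
        pds[i] = faith_pd(tree, tips)
    ratios = pds / totals if per_tree else pds / totals.mean()
    return float(ratios.mean()), float(ratios.std(ddof=0))


def parse_newick(text: str) -> PhyloTreeEnsemble:
    """Parse multi-tree Newick text (one tree per line)."""
    trees = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            dtree = dendropy.Tree.get(
                data=line, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"unparseable Newick at line {lineno}: {exc}") from exc
        try:
            trees.append(PhyloTree.from_dendropy(dtree))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return PhyloTreeEnsemble(trees)


def read_newick_trees(path) -> PhyloTreeEnsemble:
    """Read an ensemble from a multi-tree Newick file."""
    with open(path) as fh:
        text = fh.read()
    try:
        return parse_newick(text)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
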