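"""Majority-rule consensus of a posterior genealogy sample.

The consensus tree retains exactly the clades whose frequency in the
sample strictly exceeds the support threshold (default 0.5, so retained
clades are guaranteed pairwise compatible) and annotates each retained
clade with the arithmetic mean, over the sampled trees containing it, of
its MRCA coalescence time.  Those mean times drive the TMRCA lookups used
for imputation-template selection.
"""

from __future__ import annotations

import numpy as np

from ._tree import GeneTree

__all__ = ["ConsensusTree", "majority_consensus", "annotate_clade_times"]


class ConsensusTree:
    """Majority-rule clade set with supports and mean posterior times.

    Clades are stored largest-first (index 0 is the root clade covering
    all leaves); ``parent[i]`` indexes the smallest retained clade
    strictly containing clade ``i`` and ``leaf_attach[l]`` the smallest
    retained clade containing leaf ``l``.
    """

    def __init__(self, n_leaves, labels, masks_packed, support, parent, leaf_attach,
                 mean_time=None):
        self.n_leaves = int(n_leaves)
        self.labels = list(labels)
        self.masks_packed = masks_packed  # (n_clades, n_bytes) uint8
        self.support = np.asarray(support, dtype=float)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.leaf_attach = np.asarray(leaf_attach, dtype=np.int64)
        self.mean_time = (
            np.full(self.support.size, np.nan) if mean_time is None
            else np.asarray(mean_time, dtype=float)
        )

    @property
    def n_clades(self) -> int:
        return int(self.support.size)

    def clade_leafset(self, i: int) -> np.ndarray:
        return np.unpackbits(self.masks_packed[i])[: self.n_leaves].astype(bool)

    def clade_sizes(self) -> np.ndarray:
        return np.array([
            int(np.unpackbits(self.masks_packed[i]).sum()) for i in range(self.n_clades)
        ])

    def contains(self, clade: int, leaf: int) -> bool:
        return bool(self.masks_packed[clade, leaf >> 3] & (0x80 >> (leaf & 7)))

    def mrca_clade(self, a: int, b: int) -> int:
        """Smallest retained clade containing both leaves."""
        for leaf in (a, b):
            if not 0 <= leaf < self.n_leaves:
                raise ValueError(f"unknown leaf index {leaf}")
        node = int(self.leaf_attach[a])
        while not self.contains(node, b):
            node = int(self.parent[node])
        return node

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_clades)]
        for i in range(1, self.n_clades):
            ch[self.parent[i]].append(i)
        return ch

    def to_gene_tree(self) -> GeneTree:
        """Convert to a (possibly multifurcating) :class:`GeneTree` with
        node times equal to the annotated mean posterior times."""
        n = self.n_leaves
        parent = np.full(n + self.n_clades, -1, dtype=np.int32)
        time = np.concatenate([np.zeros(n), self.mean_time])
        for lf in range(n):
            parent[lf] = n + self.leaf_attach[lf]
        for i in range(1, self.n_clades):
            parent[n + i] = n + self.parent[i]
        return GeneTree(parent, time, n, labels=self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ConsensusTree(n_leaves={self.n_leaves}, n_clades={self.n_clades})"
        )


# ----------------------------------------------------------------------
def _clade_counts(trees: list[GeneTree]):
    """Count clade occurrences and accumulate MRCA times over a sample."""
    counts: dict[bytes, int] = {}
    time_sums: dict[bytes, float] = {}
    root_time_sum = 0.0
    n = trees[0].n_leaves
    for tree in trees:
        packed = tree.leaf_masks_packed()
        root = tree.root
        root_time_sum += float(tree.time[root])
        for node in range(n, tree.n_nodes):
            key = packed[node].tobytes()
            counts[key] = counts.get(key, 0) + 1
            time_sums[key] = time_sums.get(key, 0.0) + float(tree.time[node])
    return counts, time_sums, root_time_sum


def _reorder_leaves(tree: GeneTree, ref_labels: list[str]) -> GeneTree:
    """Renumber leaves so their labels follow ``ref_labels`` (internal
    node ids are preserved)."""
    if tree.labels == ref_labels:
        return tree
    pos = {lab: i for i, lab in enumerate(ref_labels)}
    old_to_new = np.arange(tree.n_nodes)
    for old_i, lab in enumerate(tree.labels):
        old_to_new[old_i] = pos[lab]
    parent = np.full(tree.n_nodes, -1, dtype=np.int32)
    time = np.empty(tree.n_nodes)
    for i in range(tree.n_nodes):
        j = old_to_new[i]
        time[j] = tree.time[i]
        p = tree.parent[i]
        parent[j] = old_to_new[p] if p >= 0 else -1
    demes = None
    if tree.demes is not None:
        demes = np.empty(tree.n_leaves, dtype=np.int32)
        for old_i in range(tree.n_leaves):
            demes[old_to_new[old_i]] = tree.demes[old_i]
    return GeneTree(parent, time, tree.n_leaves, labels=ref_labels, demes=demes)


def _resolve_trees(trees) -> list[GeneTree]:
    if hasattr(trees, "trees"):
        trees = trees.trees
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    ref = trees[0]
    out = []
    for idx, tree in enumerate(trees):
        if tree.n_leaves != ref.n_leaves or set(tree.labels) != set(ref.labels):
            raise ValueError(f"tree {idx} has a different leaf set than tree 0")
        out.append(_reorder_leaves(tree, ref.labels))
    return out


def majority_consensus(trees, threshold: float = 0.5) -> ConsensusTree:
    """Majority-rule consensus of a tree sample.

    Retains exactly the clades whose frequency strictly exceeds
    ``threshold`` (must be >= 0.5, which guarantees the retained clades
    are pairwise nested or disjoint); unresolved regions remain
    multifurcations.  Supports are recorded per clade; call
    :func:`annotate_clade_times` to add mean posterior coalescence times.
    """
    if not 0.5 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0.5, 1)")
    trees = _resolve_trees(trees)
    n = trees[0].n_leaves
    n_trees = len(trees)
    counts, _, _ = _clade_counts(trees)

    n_bytes = (n + 7) // 8
    root_key = np.packbits(np.ones(n, dtype=np.uint8)).tobytes()
    retained: list[tuple[bytes, float]] = []
    for key, c in counts.items():
        if key == root_key:
            continue
        if c / n_trees > threshold:
            retained.append((key, c / n_trees))
    # largest first; root clade prepended with support 1
    masks = [np.frombuffer(k, dtype=np.uint8) for k, _ in retained]
    sizes = [int(np.unpackbits(m).sum()) for m in masks]
    order = np.argsort(sizes)[::-1]
    packed = np.zeros((1 + len(retained), n_bytes), dtype=np.uint8)
    packed[0] = np.frombuffer(root_key, dtype=np.uint8)
    support = np.ones(1 + len(retained))
    for rank, oi in enumerate(order, start=1):
        packed[rank] = masks[oi]
        support[rank] = retained[oi][1]

    # nest: parent = smallest previously placed superset (clades are
    # pairwise compatible at threshold >= 0.5 -- assert all the same)
    parent = np.full(packed.shape[0], -1, dtype=np.int64)
    for i in range(1, packed.shape[0]):
        best = 0
        for j in range(1, i):
            inter = packed[i] & packed[j]
            if (inter == packed[i]).all():
                best = j  # later j are smaller or equal-sized supersets
            elif inter.any():
                raise AssertionError(
                    "incompatible clades retained; majority-rule property violated"
                )
        parent[i] = best
    leaf_attach = np.zeros(n, dtype=np.int64)
    for lf in range(n):
        byte, bit = lf >> 3, 0x80 >> (lf & 7)
        for i in range(packed.shape[0] - 1, 0, -1):  # smallest first
            if packed[i, byte] & bit:
                leaf_attach[lf] = i
                break
    return ConsensusTree(n, trees[0].labels, packed, support, parent, leaf_attach)


def annotate_clade_times(consensus: ConsensusTree, trees) -> ConsensusTree:
    """Annotate each retained clade with its mean posterior MRCA time.

    The mean is taken over the sampled trees that contain the clade; the
    root clade's time is the mean root time over all trees.  Because means
    are computed over different tree subsets a child clade's mean can
    exceed its parent's; such children are clamped to the parent's time so
    TMRCA lookups stay monotone along the tree.
    """
    trees = _resolve_trees(trees)
    counts, time_sums, root_time_sum = _clade_counts(trees)
    n_trees = len(trees)
    mean_time = np.empty(consensus.n_clades)
    mean_time[0] = root_time_sum / n_trees
    for i in range(1, consensus.n_clades):
        key = consensus.masks_packed[i].tobytes()
        if key not in counts:
            raise ValueError(
                "consensus clade absent from the tree sample; annotate with "
                "the sample the consensus was built from"
            )
        mean_time[i] = time_sums[key] / counts[key]
    # monotonicity repair, parents first (clades are sorted largest-first
    # and parents always precede children)
    for i in range(1, consensus.n_clades):
        p = consensus.parent[i]
        if mean_time[i] > mean_time[p]:
            mean_time[i] = mean_time[p]
    consensus.mean_time = mean_time
    return consensus
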